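"""Seeded synthetic-data generators for end-to-end pipeline verification.

No experimental spectra are deposited for this kind of assay, so the
package verifies itself by parameter recovery: generators plant known
binding constants, quantum-yield deltas, digestion rates and retention
fractions, synthesise the observables the analysis modules consume (with
realistic noise), and attach the noiseless truth so tests can compare
recovered values against planted ones.

The digestion forward model — exponential structure loss with
occupancy-dependent DNase inhibition — is an emulator for exercising the
inverse pipeline, not a mechanistic claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from doxorigami.aggregation import AggregationSample
from doxorigami.binding import (
    BindingParameters,
    DEFAULT_CHANNELS,
    TitrationSeries,
    forward_delta,
    fraction_bound,
    solve_free_bp,
)
from doxorigami.designs import DonDesign, default_registry, eps260_per_nt
from doxorigami.digestion import DigestionTimeCourse
from doxorigami.errors import ValidationError


def default_planted_params(channels: tuple[float, ...] = DEFAULT_CHANNELS) -> BindingParameters:
    """Planted binding parameters used by default in all generators.

    K11 = 2.0e5 M^-1, K12 = 2.6e5 M^-1 with quantum-yield deltas
    Phi_d11 = -0.48 and Phi_d12 = -0.933 on every channel (the 1:1 complex
    retains ~half the free-DOX quantum yield, the 1:2 complex is almost
    fully quenched), and 494 nm extinction deltas of -4200 and -3300
    M^-1 cm^-1 (both complexes moderately hypochromic).
    """
    return BindingParameters(
        k11=2.0e5,
        k12=2.6e5,
        phi_delta_11={ch: -0.48 for ch in channels},
        phi_delta_12={ch: -0.933 for ch in channels},
        eps_delta_11={494.0: -4200.0},
        eps_delta_12={494.0: -3300.0},
    )


@dataclass(frozen=True)
class DigestionModel:
    """Forward model for synthetic digestion: ``s(t) = exp(-k_eff t)``.

    ``k_eff = k_dig / (1 + inhibition * bound_dox_per_bp)`` couples the
    planted binding equilibrium to DNase inhibition by bound drug.
    ``k_dig`` is in min^-1; with the default 0.25 min^-1 a drug-free
    digestion is >= 99% complete within ~20 min.
    """

    k_dig: float = 0.25
    inhibition: float = 5.0
    hyperchromicity: float = 0.3

    def __post_init__(self) -> None:
        if self.k_dig <= 0:
            raise ValidationError("k_dig must be > 0")
        if self.inhibition < 0:
            raise ValidationError("inhibition must be >= 0")
        if self.hyperchromicity <= 0:
            raise ValidationError("hyperchromicity must be > 0")


#: Preset digestion rates: the compact 24-helix bundle digests two orders of
#: magnitude slower than the open 2D triangle.  Illustrative values.
DIGESTION_PRESETS = {
    "triangle": DigestionModel(k_dig=0.25),
    "24HB": DigestionModel(k_dig=0.0025),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Seeded configuration shared by all generators.

    The seed fixes all randomness: identical configs produce identical
    outputs.  ``noise_phi`` is the relative sigma of multiplicative
    Gaussian noise on quantum-yield proxies (shot-like, signal
    proportional); ``noise_a`` is the additive sigma on absorbances (AU).
    """

    seed: int = 0
    noise_phi: float = 0.01
    noise_a: float = 0.002
    planted_params: BindingParameters = field(default_factory=default_planted_params)
    design: DonDesign = field(default_factory=lambda: default_registry()["triangle"])
    digestion_model: DigestionModel = field(default_factory=DigestionModel)

    def __post_init__(self) -> None:
        if self.noise_phi < 0 or self.noise_a < 0:
            raise ValidationError("noise sigmas must be >= 0")

    def with_preset(self, name: str) -> "GeneratorConfig":
        """Return a copy using a named digestion preset (triangle | 24HB)."""
        try:
            model = DIGESTION_PRESETS[name]
        except KeyError:
            known = ", ".join(sorted(DIGESTION_PRESETS))
            raise KeyError(f"unknown preset {name!r}; known presets: {known}") from None
        return replace(self, digestion_model=model)


@dataclass(frozen=True)
class SyntheticTitration:
    """A generated titration with its noiseless truth."""

    series: TitrationSeries
    truth_delta_phi: dict[float, np.ndarray]
    truth_delta_a: dict[float, np.ndarray]
    truth_params: BindingParameters


@dataclass(frozen=True)
class SyntheticDigestion:
    """A generated digestion time course with its noiseless truth."""

    course: DigestionTimeCourse
    truth_percent_intact: np.ndarray
    truth_percent_released: np.ndarray | None
    truth_f_b: np.ndarray | None
    truth_k_eff: float


def gen_titration(
    config: GeneratorConfig,
    c_dox_total: float = 3e-6,
    bp_grid: np.ndarray | None = None,
    *,
    with_absorbance: bool = False,
    path_cm: float = 1.0,
) -> SyntheticTitration:
    """Generate a fluorescence (and optionally absorbance) titration series.

    Defaults emulate titrating DNA base pairs into 3 uM DOX over a
    0–40 bp/DOX molar-ratio grid.  For each total bp concentration the
    mass balance is solved with the planted constants, the 1:2 isotherm is
    evaluated per channel, and noise is applied (multiplicative on the
    Phi_0-normalised observable ``1 + dPhi``, additive on absorbance).
    """
    p = config.planted_params
    if bp_grid is None:
        ratios = np.array([0, 0.5, 1, 2, 4, 6, 9, 13, 18, 24, 31, 40], dtype=float)
        bp_grid = ratios * c_dox_total
    bp_grid = np.asarray(bp_grid, dtype=float)
    if np.any(bp_grid < 0) or np.any(np.diff(bp_grid) < 0):
        raise ValidationError("bp_grid must be non-negative and ascending")
    rng = np.random.default_rng(config.seed)
    c_ub = np.array([solve_free_bp(float(c), c_dox_total, p.k11, p.k12) for c in bp_grid])

    truth_phi: dict[float, np.ndarray] = {}
    noisy_phi: dict[float, np.ndarray] = {}
    for ch in sorted(p.phi_delta_11):
        y11, y12 = p.phi_delta_11[ch], p.phi_delta_12[ch]
        truth = np.array([forward_delta(c, p.k11, p.k12, y11, y12) for c in c_ub])
        truth_phi[ch] = truth
        # noise acts on the measured proxy Phi/Phi_0 = 1 + dPhi, then the
        # reference level is subtracted back out
        proxy = (1.0 + truth) * (1.0 + config.noise_phi * rng.standard_normal(truth.size))
        noisy_phi[ch] = np.minimum(proxy - 1.0, 0.0)

    truth_a: dict[float, np.ndarray] = {}
    noisy_a: dict[float, np.ndarray] = {}
    if with_absorbance:
        for wl in sorted(p.eps_delta_11):
            e11, e12 = p.eps_delta_11[wl], p.eps_delta_12[wl]
            denom = 1.0 + p.k11 * c_ub + p.k11 * p.k12 * c_ub**2
            theta11 = p.k11 * c_ub / denom
            theta12 = p.k11 * p.k12 * c_ub**2 / denom
            truth = (e11 * theta11 + e12 * theta12) * c_dox_total * path_cm
            truth_a[wl] = truth
            noisy_a[wl] = truth + config.noise_a * rng.standard_normal(truth.size)

    series = TitrationSeries(
        c_dox_total=c_dox_total,
        c_bp_total=bp_grid,
        delta_phi=noisy_phi,
        delta_a=noisy_a,
        design=config.design,
        path_cm=path_cm,
    )
    return SyntheticTitration(
        series=series,
        truth_delta_phi=truth_phi,
        truth_delta_a=truth_a,
        truth_params=p,
    )


def gen_digestion(
    config: GeneratorConfig,
    c_dox_total: float = 3e-6,
    t_grid: np.ndarray | None = None,
    *,
    c_don: float = 2e-9,
    channel: float = 494.0,
    coupled_release: bool = False,
) -> SyntheticDigestion:
    """Generate a DNase I digestion time course.

    The intact double-stranded fraction decays as ``exp(-k_eff t)`` with
    ``k_eff`` slowed by the planted bound-DOX density; A260 interpolates
    between the intact and digested plateaus in proportion to the digested
    fraction.  Defaults emulate 2 nM DONs digested by DNase I.

    Release coupling: by default the bound fraction at each time point is
    the binding equilibrium over the remaining base pairs, which makes
    release lag digestion while excess base pairs buffer the drug.  With
    ``coupled_release=True`` the planted % released is instead tied
    one-to-one to the digested fraction (release driven purely by structure
    loss), which is the regime where % released and % digested correlate
    perfectly.
    """
    p = config.planted_params
    model = config.digestion_model
    if t_grid is None:
        t_end = min(5.0 / model.k_dig, 120.0)
        t_grid = np.linspace(0.0, t_end, 25)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValidationError("t_grid must be strictly increasing and start at 0")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))

    design = config.design
    c_bp0 = c_don * design.n_ds / 2.0
    c_nt = c_don * (design.n_ds + design.n_ss)
    a260_intact = eps260_per_nt(design) * c_nt
    a260_digested = a260_intact * (1.0 + model.hyperchromicity)

    if c_dox_total > 0:
        c_ub0 = solve_free_bp(c_bp0, c_dox_total, p.k11, p.k12)
        bound_per_bp = fraction_bound(c_ub0, p.k11, p.k12) * c_dox_total / c_bp0
    else:
        bound_per_bp = 0.0
    k_eff = model.k_dig / (1.0 + model.inhibition * bound_per_bp)

    s = np.exp(-k_eff * t_grid)  # intact ds fraction
    truth_pct_intact = 100.0 * s
    a260_true = a260_intact + (a260_digested - a260_intact) * (1.0 - s)
    a260 = a260_true + config.noise_a * rng.standard_normal(t_grid.size)

    phi_obs = None
    truth_released = None
    truth_f_b = None
    if c_dox_total > 0:
        y11, y12 = p.phi_delta_11[channel], p.phi_delta_12[channel]
        f_b = np.empty_like(t_grid)
        dphi = np.empty_like(t_grid)
        if coupled_release:
            c_ub0 = solve_free_bp(c_bp0, c_dox_total, p.k11, p.k12)
            f_b0 = fraction_bound(c_ub0, p.k11, p.k12)
            f_b = f_b0 * s
            for i, f in enumerate(f_b):
                # invert f_b -> c_ub (positive root of the speciation quadratic)
                target = f / (1.0 - f) if f < 1.0 else np.inf
                a, b = p.k11 * p.k12, p.k11
                c_ub = (-b + np.sqrt(b * b + 4.0 * a * target)) / (2.0 * a)
                dphi[i] = forward_delta(c_ub, p.k11, p.k12, y11, y12)
        else:
            for i, frac in enumerate(s):
                c_bp_t = c_bp0 * frac
                c_ub = solve_free_bp(c_bp_t, c_dox_total, p.k11, p.k12)
                f_b[i] = fraction_bound(c_ub, p.k11, p.k12)
                dphi[i] = forward_delta(c_ub, p.k11, p.k12, y11, y12)
        truth_f_b = f_b
        truth_released = 100.0 * (f_b[0] - f_b) / f_b[0]
        proxy = (1.0 + dphi) * (1.0 + config.noise_phi * rng.standard_normal(t_grid.size))
        phi_obs = np.minimum(proxy, 1.0)

    course = DigestionTimeCourse(
        times=t_grid,
        a260=a260,
        a260_intact=a260_intact,
        a260_digested=a260_digested,
        phi_obs=phi_obs,
        c_dox_total=c_dox_total,
        design=design,
        dnase_units_per_ml=34.0,
        label=f"synthetic-{design.name}",
    )
    return SyntheticDigestion(
        course=course,
        truth_percent_intact=truth_pct_intact,
        truth_percent_released=truth_released,
        truth_f_b=truth_f_b,
        truth_k_eff=k_eff,
    )


def gen_aggregation(
    config: GeneratorConfig,
    c0_list: np.ndarray,
    retention_fractions: np.ndarray,
    *,
    c_bp: float = 18e-6,
    eps480: float = 11500.0,
    path_cm: float = 1.0,
) -> tuple[list[AggregationSample], np.ndarray]:
    """Generate aggregation samples with planted retention fractions.

    For each (c0, retention) pair, synthesises the t = 0 and supernatant
    A480 values (Beer–Lambert with a free-DOX eps480, additive noise on the
    supernatant reading) and returns the samples plus the planted
    ``c_aggregate`` truth array.
    """
    c0_list = np.asarray(c0_list, dtype=float)
    retention = np.asarray(retention_fractions, dtype=float)
    if c0_list.shape != retention.shape:
        raise ValidationError("c0_list and retention_fractions must align")
    if np.any((retention < 0) | (retention > 1)):
        raise ValidationError("retention fractions must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    samples = []
    truth = (1.0 - retention) * c0_list
    for i, (c0, r) in enumerate(zip(c0_list, retention)):
        a0 = eps480 * c0 * path_cm
        a_sup = max(r * a0 + config.noise_a * rng.standard_normal(), 0.0)
        samples.append(
            AggregationSample(
                c0=float(c0),
                a480_t0=a0,
                a480_supernatant=float(min(a_sup, a0)),
                c_bp=c_bp,
                label=f"synthetic-{i}",
            )
        )
    return samples, truth
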