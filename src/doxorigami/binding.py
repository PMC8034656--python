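"""The 1:2 DOX–base-pair thermodynamic binding model.

DOX binds double-stranded DNA in two sequential equilibria with the base
pair (bp) as the guest::

    DOX + bp      <->  DOX.bp     K11  [M^-1]
    DOX.bp + bp   <->  DOX.bp2    K12  [M^-1]

The change of an observed physical property Y (fluorescence quantum yield
or absorbance) relative to free DOX follows the 1:2 isotherm

    dY_obs = (y11*K11*c + y12*K11*K12*c^2) / (1 + K11*c + K11*K12*c^2)

with ``c = c(bp)_ub`` the concentration of unbound base pairs, itself the
physical root of the cubic mass balance

    A c^3 + B c^2 + C c - c(bp)0 = 0,
    A = K11*K12
    B = K11*(2*K12*c(DOX)0 - K12*c(bp)0 + 1)
    C = K11*(c(DOX)0 - c(bp)0) + 1.

All deltas are "complex minus free", hence <= 0 for fluorescence quenching
and hypochromicity.  Quantum-yield proxies are normalised by the free-DOX
reference (Phi/Phi_0), so quantum-yield deltas are dimensionless in [-1, 0].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.optimize import brentq

from doxorigami.designs import DonDesign
from doxorigami.errors import DomainError, FitError, SaturationError, ValidationError

#: Emission excitation channels used in the joint titration fit (nm).
DEFAULT_CHANNELS = (450.0, 460.0, 470.0, 480.0, 494.0)

#: Default seed for multi-start jitter in the titration fit.
DEFAULT_FIT_SEED = 20210228


@dataclass(frozen=True)
class BindingParameters:
    """Fitted 1:2 binding parameters.

    ``k11`` and ``k12`` are shared across channels; quantum-yield deltas
    (``phi_delta_11``, ``phi_delta_12``, Phi_0-normalised, in [-1, 0]) are
    keyed by excitation channel (nm), extinction deltas (M^-1 cm^-1) by
    analysis wavelength (nm).  ``uncertainties`` maps parameter names to
    standard errors where available.
    """

    k11: float
    k12: float
    phi_delta_11: dict[float, float] = field(default_factory=dict)
    phi_delta_12: dict[float, float] = field(default_factory=dict)
    eps_delta_11: dict[float, float] = field(default_factory=dict)
    eps_delta_12: dict[float, float] = field(default_factory=dict)
    uncertainties: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.k11 > 0 and self.k12 > 0):
            raise ValidationError("binding constants must be > 0")
        for name, deltas in (("phi_delta_11", self.phi_delta_11),
                             ("phi_delta_12", self.phi_delta_12)):
            for ch, d in deltas.items():
                if not (-1.0 - 1e-9 <= d <= 1e-9):
                    raise ValidationError(
                        f"{name}[{ch:g}] = {d:g} outside [-1, 0]: Phi_0-normalised "
                        "quenching deltas must lie in [-1, 0]"
                    )

    def phi_deltas(self, channel: float) -> tuple[float, float]:
        """(Phi_d11, Phi_d12) for one excitation channel."""
        try:
            return self.phi_delta_11[channel], self.phi_delta_12[channel]
        except KeyError:
            known = ", ".join(f"{c:g}" for c in sorted(self.phi_delta_11))
            raise KeyError(f"no deltas for channel {channel:g} nm; have {known}") from None


@dataclass(frozen=True)
class TitrationSeries:
    """One titration: DNA base pairs titrated into a fixed total DOX pool.

    ``c_bp_total`` is the non-decreasing grid of total base-pair
    concentrations (M, first point may be 0), ``delta_phi`` maps an
    excitation channel (nm) to the observed Phi_0-normalised quantum-yield
    changes, ``delta_a`` optionally maps an analysis wavelength (nm) to
    observed absorbance changes (AU).
    """

    c_dox_total: float
    c_bp_total: np.ndarray
    delta_phi: dict[float, np.ndarray]
    delta_a: dict[float, np.ndarray] = field(default_factory=dict)
    design: DonDesign | None = None
    path_cm: float = 1.0
    noise_tolerance: float = 0.05

    def __post_init__(self) -> None:
        cbp = np.asarray(self.c_bp_total, dtype=float)
        object.__setattr__(self, "c_bp_total", cbp)
        object.__setattr__(
            self, "delta_phi", {ch: np.asarray(v, dtype=float) for ch, v in self.delta_phi.items()}
        )
        object.__setattr__(
            self, "delta_a", {wl: np.asarray(v, dtype=float) for wl, v in self.delta_a.items()}
        )
        if self.c_dox_total <= 0:
            raise ValidationError("c_dox_total must be > 0")
        if cbp.ndim != 1 or cbp.size < 2:
            raise ValidationError("need at least 2 titration points")
        if np.any(cbp < 0) or np.any(np.diff(cbp) < 0):
            raise ValidationError("c_bp_total must be non-negative and non-decreasing")
        for ch, v in self.delta_phi.items():
            if v.shape != cbp.shape:
                raise ValidationError(f"channel {ch:g}: length mismatch with c_bp_total")
            if np.any(v > self.noise_tolerance):
                raise ValidationError(
                    f"channel {ch:g}: delta_phi > 0 beyond noise tolerance (quenching only)"
                )
        for wl, v in self.delta_a.items():
            if v.shape != cbp.shape:
                raise ValidationError(f"wavelength {wl:g}: length mismatch with c_bp_total")

    @property
    def n_points(self) -> int:
        return int(self.c_bp_total.size)

    @property
    def channels(self) -> tuple[float, ...]:
        return tuple(sorted(self.delta_phi))


def forward_delta(c_bp_ub: float, k11: float, k12: float, y11: float, y12: float) -> float:
    """Observable change for unbound base-pair concentration ``c_bp_ub``.

    Evaluates the 1:2 isotherm; at c = 0 returns 0 (free DOX), in the
    saturation limit returns ``y12``.
    """
    if c_bp_ub < 0:
        raise DomainError(f"negative unbound bp concentration {c_bp_ub}")
    if k11 <= 0 or k12 <= 0:
        raise DomainError("binding constants must be > 0")
    c = c_bp_ub
    denom = 1.0 + k11 * c + k11 * k12 * c * c
    return (y11 * k11 * c + y12 * k11 * k12 * c * c) / denom


def _mass_balance_coeffs(c_bp_total: float, c_dox_total: float, k11: float, k12: float):
    a = k11 * k12
    b = k11 * (2.0 * k12 * c_dox_total - k12 * c_bp_total + 1.0)
    c = k11 * (c_dox_total - c_bp_total) + 1.0
    return a, b, c


def solve_free_bp(c_bp_total: float, c_dox_total: float, k11: float, k12: float) -> float:
    """Unbound base-pair concentration from the cubic mass balance.

    Solves ``A c^3 + B c^2 + C c - c(bp)0 = 0`` for the physical root in
    ``[0, c(bp)0]``: analytic (companion-matrix) candidates are filtered to
    that interval and polished by bracketed root refinement on the
    mass-balance residual.  The returned root satisfies the residual to
    better than 1e-9 relative.
    """
    if c_bp_total < 0 or c_dox_total < 0:
        raise DomainError("concentrations must be >= 0")
    if k11 <= 0 or k12 <= 0:
        raise DomainError("binding constants must be > 0")
    if c_bp_total == 0.0:
        return 0.0
    if c_dox_total == 0.0:
        return c_bp_total  # the cubic cancels identically at c = c(bp)0
    a, b, c = _mass_balance_coeffs(c_bp_total, c_dox_total, k11, k12)

    def residual(x: float) -> float:
        return ((a * x + b) * x + c) * x - c_bp_total

    # residual(0) < 0 and residual(c_bp_total) > 0, so a bracket always exists
    lo, hi = 0.0, c_bp_total
    candidates = np.roots([a, b, c, -c_bp_total])
    real = candidates[np.abs(candidates.imag) < 1e-8 * (1.0 + np.abs(candidates.real))].real
    best = None
    for cand in real:
        x = float(min(max(cand, lo), hi))
        if best is None or abs(residual(x)) < abs(residual(best)):
            best = x
    root = brentq(residual, lo, hi, xtol=1e-30, rtol=8.9e-16, maxiter=200)
    if best is not None and abs(residual(best)) < abs(residual(root)):
        root = best
    root = float(min(max(root, 0.0), c_bp_total))
    scale = max(abs(a) * root**3, abs(b) * root**2, abs(c) * root, c_bp_total)
    if abs(residual(root)) > 1e-9 * scale:
        raise FitError(
            f"mass-balance residual {residual(root):.3e} exceeds tolerance for "
            f"c(bp)0={c_bp_total:g}, c(DOX)0={c_dox_total:g}"
        )
    return root


def fraction_bound(c_bp_ub: float, k11: float, k12: float) -> float:
    """Fraction of total DOX bound at unbound bp concentration ``c_bp_ub``.

    ``f_b = 1 - 1/(1 + K11 c + K11 K12 c^2)``; monotone increasing in c,
    0 at c = 0, -> 1 at saturation.
    """
    if c_bp_ub < 0:
        raise DomainError(f"negative unbound bp concentration {c_bp_ub}")
    c = c_bp_ub
    return 1.0 - 1.0 / (1.0 + k11 * c + k11 * k12 * c * c)


def max_bound_per_bp(c_dox_total: float, k11: float) -> float:
    """Low-bp limit of bound DOX per total base pair (closed form).

    As ``c(bp)0 -> 0`` every base pair competes for the same DOX pool and
    the ratio ``c(DOX)_b / c(bp)0`` tends to
    ``K11 c(DOX)0 / (1 + K11 c(DOX)0)``.
    """
    if c_dox_total <= 0 or k11 <= 0:
        raise DomainError("inputs must be > 0")
    x = k11 * c_dox_total
    return x / (1.0 + x)


def max_bound_per_bp_numerical(
    c_dox_total: float,
    k11: float,
    k12: float,
    *,
    bp_grid: np.ndarray | None = None,
    rtol: float = 1e-3,
) -> float:
    """Numerical variant of :func:`max_bound_per_bp`.

    Scans ``c(bp)0 -> 0`` through the full mass balance, computing
    ``c(DOX)_b / c(bp)0`` at each grid point, and verifies convergence of
    the limit before returning it.
    """
    if bp_grid is None:
        bp_grid = c_dox_total * np.logspace(-2, -6, 9)
    bp_grid = np.asarray(bp_grid, dtype=float)
    if np.any(bp_grid <= 0):
        raise DomainError("bp_grid must be positive")
    ratios = []
    for c_bp0 in np.sort(bp_grid)[::-1]:
        c_ub = solve_free_bp(c_bp0, c_dox_total, k11, k12)
        c_bound = fraction_bound(c_ub, k11, k12) * c_dox_total
        ratios.append(c_bound / c_bp0)
    if abs(ratios[-1] - ratios[-2]) > rtol * abs(ratios[-1]):
        raise FitError("low-bp limit did not converge on the supplied grid")
    return float(ratios[-1])


def invert_quantum_yield(
    delta_phi_obs: float,
    k11: float,
    k12: float,
    phi_delta_11: float,
    phi_delta_12: float,
    *,
    rtol: float = 1e-6,
) -> float:
    """Unbound bp concentration from an observed quantum-yield change.

    Solves the quadratic rearrangement of the 1:2 isotherm

        (K11 K12 (dPhi - Phi_d12)) c^2 + (K11 (dPhi - Phi_d11)) c + dPhi = 0

    and returns the unique non-negative root, verified to round-trip through
    :func:`forward_delta`.  At full saturation (``dPhi = Phi_d12``) the
    leading coefficient vanishes and a :class:`SaturationError` is raised:
    treat the bound fraction as 1 instead.
    """
    if delta_phi_obs > 0:
        raise DomainError(f"delta_phi_obs = {delta_phi_obs:g} > 0: quenching only")
    if delta_phi_obs == 0.0:
        return 0.0
    sat_gap = delta_phi_obs - phi_delta_12
    if abs(sat_gap) <= 1e-12 * max(abs(phi_delta_12), 1e-30):
        raise SaturationError(
            "observable at the 1:2 saturation limit; the inversion is degenerate "
            "(treat f_b as 1)"
        )
    if sat_gap < 0:
        raise DomainError(
            f"delta_phi_obs = {delta_phi_obs:g} below the saturation limit "
            f"Phi_d12 = {phi_delta_12:g}: outside the physical range"
        )
    a = k11 * k12 * sat_gap
    b = k11 * (delta_phi_obs - phi_delta_11)
    c0 = delta_phi_obs
    # a > 0 and c0 < 0, so the quadratic has exactly one positive root;
    # use the numerically stable branch.
    disc = b * b - 4.0 * a * c0
    q = -0.5 * (b + np.copysign(np.sqrt(disc), b))
    roots = [r for r in (q / a, c0 / q if q != 0 else np.inf) if np.isfinite(r) and r >= 0]
    if not roots:
        raise DomainError("no non-negative root for the supplied observable")
    for root in sorted(roots):
        back = forward_delta(root, k11, k12, phi_delta_11, phi_delta_12)
        if abs(back - delta_phi_obs) <= rtol * max(abs(delta_phi_obs), 1e-30):
            return float(root)
    raise FitError(
        "inversion round trip failed: no candidate root reproduces the observable"
    )


@dataclass(frozen=True)
class TitrationFitConfig:
    """Settings for the joint fluorescence titration fit."""

    log10_k_bounds: tuple[float, float] = (0.0, 9.0)
    log10_k_grid: tuple[float, ...] = (3.5, 5.0, 6.5)
    jitter: float = 0.1
    seed: int = DEFAULT_FIT_SEED
    min_points: int = 6
    min_span_factor: float = 10.0


def _model_delta_phi(
    c_bp_total: np.ndarray,
    c_dox_total: float,
    k11: float,
    k12: float,
    y11: float,
    y12: float,
) -> np.ndarray:
    out = np.empty_like(c_bp_total)
    for i, c_bp0 in enumerate(c_bp_total):
        c_ub = solve_free_bp(float(c_bp0), c_dox_total, k11, k12)
        out[i] = forward_delta(c_ub, k11, k12, y11, y12)
    return out


def fit_fluorescence_titration(
    series: TitrationSeries,
    config: TitrationFitConfig | None = None,
) -> BindingParameters:
    """Joint nonlinear least-squares fit of the 1:2 binding model.

    K11 and K12 are shared across all emission channels; each channel gets
    its own quantum-yield deltas (Phi_d11, Phi_d12).  Every residual
    evaluates the isotherm at the mass-balance root, so the fit is exact in
    the depletion of both DOX and base pairs.  K values are fitted in
    log10 space from a multi-start grid; standard errors come from the
    Jacobian at the best solution.
    """
    config = config or TitrationFitConfig()
    if not series.delta_phi:
        raise ValidationError("series has no fluorescence channels")
    if series.n_points < config.min_points:
        raise ValidationError(
            f"need at least {config.min_points} titration points, got {series.n_points}"
        )
    positive = series.c_bp_total[series.c_bp_total > 0]
    if positive.size == 0 or positive.max() / positive.min() < config.min_span_factor:
        raise ValidationError(
            f"titration must span at least a {config.min_span_factor:g}-fold range "
            "of positive c(bp)0"
        )
    channels = series.channels
    observed = np.concatenate([series.delta_phi[ch] for ch in channels])
    c_bp = series.c_bp_total
    c_dox = series.c_dox_total

    def residuals(params: lmfit.Parameters) -> np.ndarray:
        k11 = 10.0 ** params["log10_k11"].value
        k12 = 10.0 ** params["log10_k12"].value
        res = []
        c_ub = np.array([solve_free_bp(float(c), c_dox, k11, k12) for c in c_bp])
        for ch in channels:
            y11 = params[f"phi_d11_{_pname(ch)}"].value
            y12 = params[f"phi_d12_{_pname(ch)}"].value
            denom = 1.0 + k11 * c_ub + k11 * k12 * c_ub**2
            model = (y11 * k11 * c_ub + y12 * k11 * k12 * c_ub**2) / denom
            res.append(model - series.delta_phi[ch])
        return np.concatenate(res)

    rng = np.random.default_rng(config.seed)
    lo, hi = config.log10_k_bounds
    best = None
    for g11 in config.log10_k_grid:
        for g12 in config.log10_k_grid:
            params = lmfit.Parameters()
            params.add("log10_k11", value=np.clip(g11 + rng.uniform(-1, 1) * config.jitter, lo, hi),
                       min=lo, max=hi)
            params.add("log10_k12", value=np.clip(g12 + rng.uniform(-1, 1) * config.jitter, lo, hi),
                       min=lo, max=hi)
            for ch in channels:
                obs = series.delta_phi[ch]
                d12_init = float(np.clip(obs.min(), -1.0, -1e-6))
                params.add(f"phi_d11_{_pname(ch)}", value=0.5 * d12_init, min=-1.0, max=0.0)
                params.add(f"phi_d12_{_pname(ch)}", value=d12_init, min=-1.0, max=0.0)
            try:
                result = lmfit.minimize(residuals, params, method="least_squares")
            except Exception:
                continue
            if best is None or result.chisqr < best.chisqr:
                best = result
    if best is None or not best.success:
        raise FitError("titration fit failed to converge from every start")

    p = best.params
    at_bounds = [
        name for name in ("log10_k11", "log10_k12")
        if np.isclose(p[name].value, p[name].min) or np.isclose(p[name].value, p[name].max)
    ]
    if at_bounds:
        warnings.warn(f"fitted parameters at bounds: {at_bounds}", stacklevel=2)
    k11 = 10.0 ** p["log10_k11"].value
    k12 = 10.0 ** p["log10_k12"].value
    unc: dict[str, float] = {}
    if p["log10_k11"].stderr is not None:
        # delta method: sigma_K = K ln(10) sigma_log10K
        unc["k11"] = k11 * np.log(10.0) * p["log10_k11"].stderr
    if p["log10_k12"].stderr is not None:
        unc["k12"] = k12 * np.log(10.0) * p["log10_k12"].stderr
    phi11: dict[float, float] = {}
    phi12: dict[float, float] = {}
    for ch in channels:
        n11, n12 = f"phi_d11_{_pname(ch)}", f"phi_d12_{_pname(ch)}"
        phi11[ch] = float(np.clip(p[n11].value, -1.0, 0.0))
        phi12[ch] = float(np.clip(p[n12].value, -1.0, 0.0))
        if p[n11].stderr is not None:
            unc[f"phi_delta_11[{ch:g}]"] = p[n11].stderr
        if p[n12].stderr is not None:
            unc[f"phi_delta_12[{ch:g}]"] = p[n12].stderr
    return BindingParameters(
        k11=k11, k12=k12, phi_delta_11=phi11, phi_delta_12=phi12, uncertainties=unc
    )


def _pname(channel: float) -> str:
    return f"{channel:g}".replace(".", "p").replace("-", "m")


def fit_absorbance_deltas(
    series: TitrationSeries, k11: float, k12: float
) -> dict[float, tuple[float, float]]:
    """Per-wavelength extinction deltas with the binding constants fixed.

    With K11, K12 known (from the fluorescence fit) the isotherm is linear
    in the deltas: ``dA = (eps_d11*theta11 + eps_d12*theta12) * c(DOX)0 *
    path`` where theta are the 1:1 / 1:2 complex mole fractions of DOX at
    the mass-balance root.  Solved per wavelength by linear least squares.
    Returns ``{wavelength: (eps_d11, eps_d12)}``.
    """
    if not series.delta_a:
        raise ValidationError("series carries no absorbance deltas")
    if series.n_points < 2:
        raise ValidationError("need at least 2 points for the linear solve")
    c_ub = np.array(
        [solve_free_bp(float(c), series.c_dox_total, k11, k12) for c in series.c_bp_total]
    )
    denom = 1.0 + k11 * c_ub + k11 * k12 * c_ub**2
    theta11 = k11 * c_ub / denom
    theta12 = k11 * k12 * c_ub**2 / denom
    design = np.column_stack([theta11, theta12]) * series.c_dox_total * series.path_cm
    if np.linalg.matrix_rank(design, tol=1e-12 * np.abs(design).max()) < 2:
        warnings.warn(
            "absorbance design matrix is rank-deficient (all points in one binding "
            "regime); deltas are poorly conditioned",
            stacklevel=2,
        )
    out: dict[float, tuple[float, float]] = {}
    for wl, da in series.delta_a.items():
        coef, *_ = np.linalg.lstsq(design, da, rcond=None)
        out[wl] = (float(coef[0]), float(coef[1]))
    return out


@dataclass(frozen=True)
class ExponentialFit:
    """Result of the 1-component exponential decay fit ``a e^{-b t} + c``."""

    a: float
    b: float
    c: float
    stderr: dict[str, float]
    no_decay: bool

    @property
    def half_life(self) -> float:
        """``ln 2 / b``; infinite when no decay was resolved."""
        return float(np.inf) if self.b == 0 else float(np.log(2.0) / self.b)


def fit_exponential_kinetics(times: np.ndarray, values: np.ndarray) -> ExponentialFit:
    """Fit ``a * exp(-b t) + c`` to an equilibration time course.

    Used to summarise loading kinetics (how fast the observable settles
    after mixing DOX and DONs).  Needs >= 4 points; constant data yields
    ``b = 0`` with the ``no_decay`` flag set.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size:
        raise ValidationError("times and values must have equal length")
    if t.size < 4:
        raise ValidationError(f"need at least 4 points, got {t.size}")
    if np.any(np.diff(t) < 0):
        raise ValidationError("times must be non-decreasing")
    spread = v.max() - v.min()
    if spread <= 1e-12 * max(abs(v).max(), 1.0):
        return ExponentialFit(a=0.0, b=0.0, c=float(v.mean()), stderr={}, no_decay=True)

    t_span = t[-1] - t[0]
    params = lmfit.Parameters()
    params.add("a", value=float(v[0] - v[-1]))
    params.add("b", value=3.0 / t_span if t_span > 0 else 1.0, min=0.0)
    params.add("c", value=float(v[-1]))

    def residuals(p: lmfit.Parameters) -> np.ndarray:
        return p["a"].value * np.exp(-p["b"].value * t) + p["c"].value - v

    result = lmfit.minimize(residuals, params, method="least_squares")
    if not result.success:
        raise FitError("exponential kinetics fit failed to converge")
    p = result.params
    stderr = {k: p[k].stderr for k in ("a", "b", "c") if p[k].stderr is not None}
    no_decay = bool(np.isclose(p["b"].value, 0.0))
    return ExponentialFit(
        a=float(p["a"].value), b=float(p["b"].value), c=float(p["c"].value),
        stderr=stderr, no_decay=no_decay,
    )


def loading_density_increase(density_low: float, density_high: float) -> float:
    """Percent increase of a DOX/bp loading density (e.g. 0.17 -> 0.25 is ~47%)."""
    if density_low <= 0:
        raise DomainError("reference density must be > 0")
    return 100.0 * (density_high - density_low) / density_low


def dissociation_half_time(k_off: float) -> float:
    """Equilibration half-time ``ln 2 / k_off`` (s) from a dissociation rate (s^-1)."""
    if k_off <= 0:
        raise DomainError("k_off must be > 0")
    return float(np.log(2.0) / k_off)
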