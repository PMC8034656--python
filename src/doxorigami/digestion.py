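"""DNase I digestion analysis: structural integrity and DOX release.

Digestion of double-stranded DNA raises its 260 nm absorbance
(hyperchromicity); the fraction of intact double-stranded residues is read
off the A260 trace between its intact and fully-digested plateaus.  As the
carrier is digested, bound DOX is released and its fluorescence quantum
yield recovers towards the free-DOX reference; inverting the 1:2 binding
isotherm per time point converts the recovery into a bound fraction and a
percentage of released drug.  Rates are estimated by linear regression over
the initial linear phase, and the release rate is converted into a
"relative dose" — moles of DOX released per minute — by multiplying with
the bound-DOX concentration of the intact sample.

Note on orientation: the progress ratio
``(A260(t) - A260(intact)) / (A260(digested) - A260(intact))`` is 0 before
DNase addition and 100% at completion, i.e. it measures digestion
*progress*; % intact is its complement, so reported curves start at 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from doxorigami.binding import (
    BindingParameters,
    fraction_bound,
    invert_quantum_yield,
)
from doxorigami.designs import DonDesign
from doxorigami.errors import DataError, DomainError, SaturationError, ValidationError
from doxorigami.spectra import FreeDoxReference

WindowRule = Literal["intact_threshold", "fixed_count", "r2_expanding"]


@dataclass(frozen=True)
class DigestionTimeCourse:
    """A DNase I digestion time course (t = 0 at enzyme addition).

    ``a260`` values are DOX-corrected; ``phi_obs`` are Phi_0-normalised
    quantum-yield proxies from 494 nm excitation (``None`` for drug-free
    runs).  ``a260_intact``/``a260_digested`` are the plateau absorbances
    before DNase addition and after completion.
    """

    times: np.ndarray
    a260: np.ndarray
    a260_intact: float
    a260_digested: float
    phi_obs: np.ndarray | None = None
    c_dox_total: float = 0.0
    design: DonDesign | None = None
    dnase_units_per_ml: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.a260, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "a260", a)
        if self.phi_obs is not None:
            phi = np.asarray(self.phi_obs, dtype=float)
            object.__setattr__(self, "phi_obs", phi)
            if phi.shape != t.shape:
                raise ValidationError("phi_obs length mismatch with times")
        if t.ndim != 1 or t.size < 2:
            raise ValidationError("need at least 2 time points")
        if a.shape != t.shape:
            raise ValidationError("a260 length mismatch with times")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing and start at >= 0")
        if not self.a260_digested > self.a260_intact:
            raise ValidationError(
                "a260_digested must exceed a260_intact (hyperchromicity on digestion)"
            )
        if self.c_dox_total < 0:
            raise ValidationError("c_dox_total must be >= 0")


@dataclass(frozen=True)
class LinearRate:
    """Slope of a linear-phase regression with its standard error."""

    rate: float
    stderr: float
    n_points: int
    window: tuple[float, float]
    r_squared: float


@dataclass(frozen=True)
class DigestionResult:
    """Derived digestion/release quantities for one time course."""

    times: np.ndarray
    percent_intact: np.ndarray
    percent_released: np.ndarray | None
    f_b: np.ndarray | None
    f_b_intact: float | None
    digestion_rate: LinearRate
    release_rate: LinearRate | None
    relative_dose: float | None
    release_digestion_correlation: float | None = None


@dataclass(frozen=True)
class LinearPhaseConfig:
    """How the initial linear phase is selected.

    ``intact_threshold`` (default): the longest initial run of points with
    % intact >= ``threshold`` (at least ``min_points`` points, extending the
    window forward if the threshold alone selects fewer).  ``fixed_count``:
    the first ``fixed_count`` points.  ``r2_expanding``: grow the window
    from ``min_points`` while the regression R^2 does not degrade.
    """

    rule: WindowRule = "intact_threshold"
    threshold: float = 70.0
    min_points: int = 4
    fixed_count: int = 5


def digestion_progress(a260_t, a260_intact: float, a260_digested: float):
    """Digestion progress in percent: 0 at the intact plateau, 100 at completion."""
    if a260_digested <= a260_intact:
        raise DomainError("a260_digested must exceed a260_intact")
    a260_t = np.asarray(a260_t, dtype=float)
    out = 100.0 * (a260_t - a260_intact) / (a260_digested - a260_intact)
    return float(out) if out.ndim == 0 else out


def percent_intact(a260_t, a260_intact: float, a260_digested: float):
    """Percent intact double-stranded residues: 100 minus digestion progress."""
    return 100.0 - digestion_progress(a260_t, a260_intact, a260_digested)


def percent_released(f_b_t, f_b_intact: float):
    """Percent of initially bound DOX released: ``100 (f_b,intact - f_b)/f_b,intact``."""
    if f_b_intact <= 0:
        raise DomainError("f_b_intact must be > 0: no bound DOX to release")
    f_b_t = np.asarray(f_b_t, dtype=float)
    out = 100.0 * (f_b_intact - f_b_t) / f_b_intact
    return float(out) if out.ndim == 0 else out


def release_series(
    course: DigestionTimeCourse,
    params: BindingParameters,
    reference: FreeDoxReference,
    *,
    channel: float = 494.0,
    noise_tolerance: float = 0.02,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-time-point bound fraction and % released from quantum-yield recovery.

    For each time point, ``dPhi_obs = Phi_obs - Phi_0`` is inverted through
    the 1:2 isotherm to the unbound bp concentration, which gives the bound
    fraction and, relative to the pre-DNase state, the released percentage.
    Returns ``(f_b, percent_released, f_b_intact)``.
    """
    if course.phi_obs is None:
        raise ValidationError("time course has no fluorescence data")
    if course.c_dox_total <= 0:
        raise ValidationError("course has no DOX (c_dox_total = 0)")
    if abs(reference.c_dox - course.c_dox_total) > 0.05 * course.c_dox_total:
        warnings.warn(
            "free-DOX reference concentration differs from the course by > 5%",
            stacklevel=2,
        )
    y11, y12 = params.phi_deltas(channel)
    # phi_obs is Phi_0-normalised, so the reference level is 1 by construction
    delta_phi = course.phi_obs - 1.0
    above = delta_phi > noise_tolerance
    if np.any(above):
        raise DataError(
            f"fluorescence above the free-DOX reference beyond tolerance at "
            f"t = {course.times[above][0]:g} min"
        )
    f_b = np.empty_like(delta_phi)
    for i, dphi in enumerate(np.minimum(delta_phi, 0.0)):
        try:
            c_ub = invert_quantum_yield(float(dphi), params.k11, params.k12, y11, y12)
        except SaturationError:
            f_b[i] = 1.0
            continue
        f_b[i] = fraction_bound(c_ub, params.k11, params.k12)
    f_b_intact = float(f_b[0])
    if f_b_intact <= 0:
        raise DataError("no bound DOX in the intact state (f_b(0) = 0)")
    released = percent_released(f_b, f_b_intact)
    if np.any(released < -5.0) or np.any(released > 105.0):
        warnings.warn(
            "% released outside [0, 100] beyond noise; values reported unclipped",
            stacklevel=2,
        )
    return f_b, released, f_b_intact


def _select_window(
    times: np.ndarray,
    pct_intact: np.ndarray,
    config: LinearPhaseConfig,
) -> np.ndarray:
    n = times.size
    if config.rule == "fixed_count":
        count = min(config.fixed_count, n)
        return np.arange(count)
    if config.rule == "intact_threshold":
        below = np.nonzero(pct_intact < config.threshold)[0]
        count = int(below[0]) if below.size else n
        count = max(count, min(config.min_points, n))
        return np.arange(count)
    if config.rule == "r2_expanding":
        best_idx = np.arange(min(config.min_points, n))
        best_r2 = _r_squared(times[best_idx], pct_intact[best_idx])
        for count in range(min(config.min_points, n) + 1, n + 1):
            idx = np.arange(count)
            r2 = _r_squared(times[idx], pct_intact[idx])
            if r2 >= best_r2 - 1e-6:
                best_idx, best_r2 = idx, max(best_r2, r2)
            else:
                break
        return best_idx
    raise ValidationError(f"unknown window rule {config.rule!r}")


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(y) == 0:
        return 1.0
    return float(stats.linregress(x, y).rvalue ** 2)


def linear_phase_rate(
    times: np.ndarray,
    values: np.ndarray,
    config: LinearPhaseConfig | None = None,
    *,
    window_values: np.ndarray | None = None,
) -> LinearRate:
    """Ordinary least-squares slope over the initial linear phase.

    The window is selected by ``config.rule`` on ``window_values`` (by
    default ``values`` itself; pass the % intact series to reuse its window
    for the release series).  Returns the slope in units of
    ``values``/min with its standard error.
    """
    config = config or LinearPhaseConfig()
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size:
        raise ValidationError("times and values must have equal length")
    wv = v if window_values is None else np.asarray(window_values, dtype=float)
    idx = _select_window(t, wv, config)
    if idx.size < 3:
        raise ValidationError(
            f"linear-phase window selected only {idx.size} points (< 3)"
        )
    if np.ptp(v[idx]) == 0:
        return LinearRate(
            rate=0.0, stderr=0.0, n_points=int(idx.size),
            window=(float(t[idx][0]), float(t[idx][-1])), r_squared=1.0,
        )
    fit = stats.linregress(t[idx], v[idx])
    return LinearRate(
        rate=float(fit.slope),
        stderr=float(fit.stderr),
        n_points=int(idx.size),
        window=(float(t[idx][0]), float(t[idx][-1])),
        r_squared=float(fit.rvalue**2),
    )


def relative_dose(release_rate: float, f_b_intact: float, c_dox_total: float) -> float:
    """Moles of DOX released per minute: ``rate/100 * f_b,intact * c(DOX)0``.

    ``release_rate`` is in %/min; the result is in M/min.
    """
    if release_rate < 0 or c_dox_total < 0 or f_b_intact < 0:
        raise DomainError("inputs must be non-negative")
    if f_b_intact > 1:
        raise DomainError("f_b_intact must be <= 1")
    return release_rate / 100.0 * f_b_intact * c_dox_total


def analyze_digestion(
    course: DigestionTimeCourse,
    params: BindingParameters | None = None,
    reference: FreeDoxReference | None = None,
    config: LinearPhaseConfig | None = None,
    *,
    channel: float = 494.0,
) -> DigestionResult:
    """Full digestion analysis of one time course.

    Computes % intact per time point and its linear-phase digestion rate;
    if the course carries DOX fluorescence (and binding parameters plus a
    free-DOX reference are given) also the release series, the release
    rate over the same time window, the relative dose, and the correlation
    between % released and digestion progress.
    """
    config = config or LinearPhaseConfig()
    pct_intact = percent_intact(course.a260, course.a260_intact, course.a260_digested)
    digestion_rate = linear_phase_rate(course.times, pct_intact, config)

    has_release = course.phi_obs is not None and course.c_dox_total > 0
    if has_release and (params is None or reference is None):
        raise ValidationError(
            "course carries DOX fluorescence: binding parameters and a free-DOX "
            "reference are required"
        )
    if not has_release:
        return DigestionResult(
            times=course.times,
            percent_intact=pct_intact,
            percent_released=None,
            f_b=None,
            f_b_intact=None,
            digestion_rate=digestion_rate,
            release_rate=None,
            relative_dose=None,
        )

    try:
        f_b, released, f_b_intact = release_series(
            course, params, reference, channel=channel
        )
    except (DataError, ValidationError) as exc:
        raise type(exc)(f"release stage: {exc}") from exc
    try:
        rel_rate = linear_phase_rate(
            course.times, released, config, window_values=pct_intact
        )
    except ValidationError as exc:
        raise ValidationError(f"release-rate stage: {exc}") from exc
    dose = relative_dose(max(rel_rate.rate, 0.0), f_b_intact, course.c_dox_total)
    progress = 100.0 - pct_intact
    corr = (
        float(np.corrcoef(released, progress)[0, 1])
        if np.ptp(released) > 0 and np.ptp(progress) > 0
        else None
    )
    return DigestionResult(
        times=course.times,
        percent_intact=pct_intact,
        percent_released=released,
        f_b=f_b,
        f_b_intact=f_b_intact,
        digestion_rate=digestion_rate,
        release_rate=rel_rate,
        relative_dose=dose,
        release_digestion_correlation=corr,
    )
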