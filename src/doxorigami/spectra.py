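"""Spectrum data model, CSV I/O and quantum-yield correction utilities.

Absorbance and emission traces are wavelength-indexed series.  Fluorescence
intensities are converted to quantum-yield proxies by dividing the integrated
emission by the absorbed light fraction ``1 - T`` at the excitation
wavelength, where ``T = 10**(-A)`` is the transmittance; this corrects for
the hypochromic loss of excitation efficiency as DOX binds DNA during a
titration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from doxorigami.errors import DomainError, ParseError, ValidationError

SpectrumKind = Literal["absorbance", "emission"]

#: Default DOX emission integration window (nm); spans the emission band
#: excited at 450-494 nm.  Configurable per call.
DEFAULT_EMISSION_WINDOW = (500.0, 700.0)


@dataclass(frozen=True)
class Spectrum:
    """One wavelength-indexed absorbance or emission trace.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelength grid in nm (length >= 2).
    values
        Absorbance (AU) or emission intensity (arbitrary counts).
    kind
        ``"absorbance"`` or ``"emission"``.
    excitation_nm
        Excitation wavelength for emission spectra; ``None`` for absorbance.
    label
        Free-text description.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: SpectrumKind
    excitation_nm: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValidationError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise ValidationError("a spectrum needs at least 2 points")
        if not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise ValidationError("wavelengths and values must be finite")
        if self.kind not in ("absorbance", "emission"):
            raise ValidationError(f"unknown spectrum kind {self.kind!r}")

    def value_at(self, wavelength_nm: float) -> float:
        """Linearly interpolated value at ``wavelength_nm``.

        Raises :class:`DomainError` outside the grid range.
        """
        wl = self.wavelengths_nm
        if not (wl[0] <= wavelength_nm <= wl[-1]):
            raise DomainError(
                f"{wavelength_nm} nm outside spectrum range [{wl[0]}, {wl[-1]}] nm"
            )
        return float(np.interp(wavelength_nm, wl, self.values))


@dataclass(frozen=True)
class FreeDoxReference:
    """Free-DOX reference measured in the same run as the samples.

    Holds the quantities needed to normalise sample observables: the total
    DOX concentration, the quantum-yield proxy of free DOX (``phi0_proxy``,
    the Phi_0 of the Phi/Phi_0 normalisation), the 260 nm absorbance of the
    DOX-only solution (subtracted from sample A260 before DNA
    quantification), and free-DOX molar extinction coefficients per analysis
    wavelength.
    """

    c_dox: float
    phi0_proxy: float
    a260_dox: float = 0.0
    eps0: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.c_dox > 0:
            raise ValidationError("c_dox must be > 0")
        if not self.phi0_proxy > 0:
            raise ValidationError("phi0_proxy must be > 0")
        if self.a260_dox < 0:
            raise ValidationError("a260_dox must be >= 0")
        if any(e <= 0 for e in self.eps0.values()):
            raise ValidationError("extinction coefficients must be > 0")


def read_spectrum_csv(path: str | Path, kind: SpectrumKind) -> Spectrum:
    """Read a two-column ``wavelength_nm,value`` CSV into a :class:`Spectrum`.

    The dialect is comma-separated UTF-8 with an optional single header row
    and optional ``#`` comment lines; emission files may carry the excitation
    wavelength in a commented header (``# excitation_nm=494``).  Rows are
    sorted by wavelength if needed (with a warning); duplicate wavelengths
    are a :class:`ParseError`.
    """
    path = Path(path)
    excitation: float | None = None
    header_seen = False
    rows: list[tuple[float, float]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("excitation_nm"):
                    try:
                        excitation = float(body.split("=", 1)[1])
                    except (IndexError, ValueError) as exc:
                        raise ParseError(
                            f"{path}:{lineno}: malformed excitation_nm header"
                        ) from exc
                continue
            cells = [c.strip() for c in line.split(",")]
            if len(cells) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(cells)}")
            try:
                rows.append((float(cells[0]), float(cells[1])))
            except ValueError:
                if not rows and not header_seen:
                    header_seen = True  # single header row allowed
                    continue
                raise ParseError(f"{path}:{lineno}: non-numeric cell in {cells!r}") from None
    if len(rows) < 2:
        raise ParseError(f"{path}: fewer than 2 data rows")
    wl = np.array([r[0] for r in rows])
    vals = np.array([r[1] for r in rows])
    uniq, counts = np.unique(wl, return_counts=True)
    if np.any(counts > 1):
        dup = uniq[counts > 1][0]
        raise ParseError(f"{path}: duplicate wavelength {dup:g} nm")
    if not np.all(np.diff(wl) > 0):
        warnings.warn(f"{path}: wavelengths not sorted; sorting", stacklevel=2)
        order = np.argsort(wl)
        wl, vals = wl[order], vals[order]
    return Spectrum(wl, vals, kind=kind, excitation_nm=excitation, label=path.stem)


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum in the same CSV dialect :func:`read_spectrum_csv` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if spectrum.excitation_nm is not None:
            fh.write(f"# excitation_nm={spectrum.excitation_nm:g}\n")
        fh.write("wavelength_nm,value\n")
        for wl, v in zip(spectrum.wavelengths_nm, spectrum.values):
            fh.write(f"{wl:.6g},{v:.8g}\n")


def transmittance(absorbance: float) -> float:
    """Transmittance ``T = 10**(-A)`` of an absorbance ``A >= 0``."""
    if absorbance < 0:
        raise DomainError(f"absorbance must be >= 0, got {absorbance}")
    return float(10.0 ** (-absorbance))


def quantum_yield_proxy(integrated_emission: float, excitation_absorbance: float) -> float:
    """Quantum-yield proxy: emission normalised by the absorbed-light fraction.

    Returns ``I / (1 - 10**(-A))`` with ``A`` the absorbance at the
    excitation wavelength.  Proportional to the fluorescence quantum yield;
    corrects integrated emission for the extinction-coefficient decrease
    during a titration.
    """
    if excitation_absorbance <= 0:
        raise DomainError(
            "excitation absorbance must be > 0: with A = 0 no light is absorbed "
            "and the quantum-yield proxy I/(1 - T) is undefined"
        )
    absorbed = 1.0 - transmittance(excitation_absorbance)
    return float(integrated_emission / absorbed)


def integrate_emission(
    spectrum: Spectrum,
    lo_nm: float = DEFAULT_EMISSION_WINDOW[0],
    hi_nm: float = DEFAULT_EMISSION_WINDOW[1],
) -> float:
    """Trapezoidal integral of an emission spectrum over ``[lo_nm, hi_nm]``.

    The window is clipped to the measured grid; grid points inside the window
    plus linearly interpolated endpoint values define the trapezoids.
    """
    if spectrum.kind != "emission":
        raise DomainError("integrate_emission requires an emission spectrum")
    if not lo_nm < hi_nm:
        raise DomainError(f"need lo < hi, got [{lo_nm}, {hi_nm}]")
    wl, vals = spectrum.wavelengths_nm, spectrum.values
    lo = max(lo_nm, float(wl[0]))
    hi = min(hi_nm, float(wl[-1]))
    if lo >= hi:
        raise DomainError(
            f"window [{lo_nm}, {hi_nm}] nm does not overlap grid [{wl[0]}, {wl[-1]}] nm"
        )
    inner = wl[(wl > lo) & (wl < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    return float(np.trapezoid(np.interp(grid, wl, vals), grid))


def subtract_reference(sample: Spectrum, reference: Spectrum, scale: float = 1.0) -> Spectrum:
    """Pointwise ``sample - scale * reference`` on the sample grid.

    Used to remove the free-DOX contribution from sample absorbance before
    quantifying DNA (e.g. the DOX A260 subtraction).  The reference is
    interpolated onto the sample grid; the two ranges must overlap the whole
    sample grid.
    """
    if sample.kind != reference.kind:
        raise DomainError("sample and reference must be the same kind")
    s_wl, r_wl = sample.wavelengths_nm, reference.wavelengths_nm
    if s_wl[0] < r_wl[0] - 1e-9 or s_wl[-1] > r_wl[-1] + 1e-9:
        raise DomainError(
            "reference does not cover the sample wavelength range: "
            f"sample [{s_wl[0]}, {s_wl[-1]}] vs reference [{r_wl[0]}, {r_wl[-1]}] nm"
        )
    ref_on_sample = np.interp(s_wl, r_wl, reference.values)
    return Spectrum(
        s_wl,
        sample.values - scale * ref_on_sample,
        kind=sample.kind,
        excitation_nm=sample.excitation_nm,
        label=f"{sample.label}-{scale:g}x{reference.label}" if sample.label else "",
    )


def subtract_scatter_baseline(spectrum: Spectrum, reference_nm: float = 700.0) -> Spectrum:
    """Subtract the absorbance at ``reference_nm`` from the whole spectrum.

    Optional correction for a scattering-elevated baseline; off by default in
    all pipelines.
    """
    if spectrum.kind != "absorbance":
        raise DomainError("scatter baseline correction applies to absorbance spectra")
    baseline = spectrum.value_at(reference_nm)
    return Spectrum(
        spectrum.wavelengths_nm,
        spectrum.values - baseline,
        kind="absorbance",
        label=spectrum.label,
    )
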