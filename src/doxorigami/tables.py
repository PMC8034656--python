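"""CSV readers/writers for titration and digestion tables.

Dialects (comma-separated UTF-8, decimal point, ``#`` metadata comments):

* titration: ``c_bp_total_M`` plus one ``delta_phi_<exnm>`` column per
  emission channel and optional ``delta_A_<nm>`` columns; total DOX in a
  ``# c_dox_total_M=...`` header.
* digestion: ``time_min,a260[,phi_obs]`` with ``# a260_intact=``,
  ``# a260_digested=`` and optional ``# c_dox_total_M=`` headers.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from doxorigami.binding import TitrationSeries
from doxorigami.designs import DonDesign
from doxorigami.digestion import DigestionResult, DigestionTimeCourse
from doxorigami.errors import ParseError

_PHI_COL = re.compile(r"^delta_phi_([0-9.]+)$")
_A_COL = re.compile(r"^delta_A_([0-9.]+)$")


def _read_metadata(path: Path) -> dict[str, float]:
    meta: dict[str, float] = {}
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, value = (p.strip() for p in body.split("=", 1))
                try:
                    meta[key] = float(value)
                except ValueError:
                    pass
    return meta


def read_titration_csv(
    path: str | Path,
    c_dox_total: float | None = None,
    design: DonDesign | None = None,
) -> TitrationSeries:
    """Read a titration table; ``c_dox_total`` may come from the header."""
    path = Path(path)
    meta = _read_metadata(path)
    c_dox = c_dox_total if c_dox_total is not None else meta.get("c_dox_total_M")
    if c_dox is None:
        raise ParseError(f"{path}: c_dox_total not given and no '# c_dox_total_M=' header")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if "c_bp_total_M" not in df.columns:
        raise ParseError(f"{path}: missing column c_bp_total_M")
    delta_phi = {}
    delta_a = {}
    for col in df.columns:
        if m := _PHI_COL.match(col):
            delta_phi[float(m.group(1))] = df[col].to_numpy(dtype=float)
        elif m := _A_COL.match(col):
            delta_a[float(m.group(1))] = df[col].to_numpy(dtype=float)
    if not delta_phi and not delta_a:
        raise ParseError(f"{path}: no delta_phi_<nm> or delta_A_<nm> columns")
    return TitrationSeries(
        c_dox_total=float(c_dox),
        c_bp_total=df["c_bp_total_M"].to_numpy(dtype=float),
        delta_phi=delta_phi,
        delta_a=delta_a,
        design=design,
    )


def write_titration_csv(series: TitrationSeries, path: str | Path) -> None:
    path = Path(path)
    cols: dict[str, np.ndarray] = {"c_bp_total_M": series.c_bp_total}
    for ch in series.channels:
        cols[f"delta_phi_{ch:g}"] = series.delta_phi[ch]
    for wl in sorted(series.delta_a):
        cols[f"delta_A_{wl:g}"] = series.delta_a[wl]
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# c_dox_total_M={series.c_dox_total:.10g}\n")
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def read_digestion_csv(
    path: str | Path,
    design: DonDesign | None = None,
) -> DigestionTimeCourse:
    """Read a digestion time-course table (metadata from ``#`` headers)."""
    path = Path(path)
    meta = _read_metadata(path)
    for key in ("a260_intact", "a260_digested"):
        if key not in meta:
            raise ParseError(f"{path}: missing '# {key}=' header")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = {"time_min", "a260"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    phi = df["phi_obs"].to_numpy(dtype=float) if "phi_obs" in df.columns else None
    return DigestionTimeCourse(
        times=df["time_min"].to_numpy(dtype=float),
        a260=df["a260"].to_numpy(dtype=float),
        a260_intact=meta["a260_intact"],
        a260_digested=meta["a260_digested"],
        phi_obs=phi,
        c_dox_total=meta.get("c_dox_total_M", 0.0),
        design=design,
        dnase_units_per_ml=meta.get("dnase_units_per_ml"),
        label=path.stem,
    )


def write_digestion_csv(course: DigestionTimeCourse, path: str | Path) -> None:
    path = Path(path)
    cols: dict[str, np.ndarray] = {"time_min": course.times, "a260": course.a260}
    if course.phi_obs is not None:
        cols["phi_obs"] = course.phi_obs
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# a260_intact={course.a260_intact:.10g}\n")
        fh.write(f"# a260_digested={course.a260_digested:.10g}\n")
        if course.c_dox_total > 0:
            fh.write(f"# c_dox_total_M={course.c_dox_total:.10g}\n")
        if course.dnase_units_per_ml is not None:
            fh.write(f"# dnase_units_per_ml={course.dnase_units_per_ml:.10g}\n")
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def write_digestion_result_csv(result: DigestionResult, path: str | Path) -> None:
    """Per-time-point result table: time_min, percent_intact[, percent_released]."""
    cols: dict[str, np.ndarray] = {
        "time_min": result.times,
        "percent_intact": result.percent_intact,
    }
    if result.percent_released is not None:
        cols["percent_released"] = result.percent_released
        cols["f_b"] = result.f_b
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def write_report(entries: dict[str, object], path: str | Path) -> None:
    """Plain-text ``key = value`` report (units embedded in key names)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for key, value in entries.items():
            if isinstance(value, float):
                fh.write(f"{key} = {value:.8g}\n")
            else:
                fh.write(f"{key} = {value}\n")
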