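"""DOX self-aggregation bookkeeping.

During loading, DOX can precipitate out of solution as self-aggregates
(driven by the low solubility of the deprotonated molecule at high pH and
by Mg2+ complexation).  Aggregation is quantified from the 480 nm
absorbance of the supernatant after incubation and centrifugation, relative
to the t = 0 absorbance: the free concentration scales with the A480 ratio
and the aggregate is the complement, ``c_aggregate = c0 - c_free``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from doxorigami.errors import DataError, DomainError, ValidationError

#: Molar mass of doxorubicin free base (g/mol), C27H29NO11.
DOX_FREE_BASE_MW = 543.52


@dataclass(frozen=True)
class AggregationSample:
    """One aggregation measurement.

    ``c0`` is the initial DOX concentration (M), ``a480_t0`` the 480 nm
    absorbance at t = 0 and ``a480_supernatant`` the A480 of the supernatant
    after incubation + centrifugation (same geometry).  ``c_bp`` is the DON
    base-pair concentration (0 for DOX-only controls).
    """

    c0: float
    a480_t0: float
    a480_supernatant: float
    c_bp: float = 0.0
    label: str = ""
    noise_tolerance: float = 0.02

    def __post_init__(self) -> None:
        if not self.c0 > 0:
            raise ValidationError("c0 must be > 0")
        if self.a480_t0 < 0 or self.a480_supernatant < 0:
            raise ValidationError("absorbances must be >= 0")
        if self.c_bp < 0:
            raise ValidationError("c_bp must be >= 0")
        if self.a480_supernatant > self.a480_t0 * (1.0 + self.noise_tolerance):
            raise ValidationError(
                f"{self.label or 'sample'}: supernatant A480 exceeds the t=0 A480 "
                "beyond noise tolerance"
            )


def c_free_from_a480(sample: AggregationSample) -> float:
    """Free DOX concentration left in the supernatant: ``c0 * A480_sup/A480_t0``."""
    if sample.a480_t0 == 0:
        raise DomainError("a480_t0 must be > 0")
    return sample.c0 * sample.a480_supernatant / sample.a480_t0


def c_aggregate(sample: AggregationSample) -> float:
    """Aggregated (precipitated) DOX concentration: ``c0 - c_free``.

    Noise can push ``c_free`` marginally above ``c0``; within the sample's
    tolerance the result is floored at 0 with a warning, beyond it a
    :class:`DataError` is raised.
    """
    c_free = c_free_from_a480(sample)
    if c_free > sample.c0 * (1.0 + sample.noise_tolerance):
        raise DataError(
            f"{sample.label or 'sample'}: c_free = {c_free:g} M exceeds c0 = "
            f"{sample.c0:g} M beyond tolerance"
        )
    agg = sample.c0 - c_free
    if agg < 0:
        warnings.warn(
            f"{sample.label or 'sample'}: c_free marginally above c0; "
            "c_aggregate floored at 0",
            stacklevel=2,
        )
        return 0.0
    return agg


def dox_per_bp(c_aggregate_m: float, c_bp: float) -> float | None:
    """DOX molecules in the precipitate per DNA base pair.

    Returns ``None`` for DOX-only controls (``c_bp = 0``); values above 1
    exceed the intercalation capacity of the DNA (one DOX per base pair is
    an upper limit for bound drug) and are flagged with a warning —
    precipitate beyond that ratio must be free-DOX aggregate.
    """
    if c_aggregate_m < 0:
        raise DomainError("c_aggregate must be >= 0")
    if c_bp == 0:
        return None
    if c_bp < 0:
        raise DomainError("c_bp must be >= 0")
    ratio = c_aggregate_m / c_bp
    if ratio > 1.0:
        warnings.warn(
            f"DOX/bp = {ratio:.3g} exceeds the intercalation capacity (1 per bp); "
            "the precipitate cannot be exclusively DNA-bound DOX",
            stacklevel=2,
        )
    return ratio


def read_aggregation_csv(path: str | Path) -> list[AggregationSample]:
    """Read samples from a CSV with columns label,c0_M,a480_t0,a480_sup,c_bp_M."""
    df = pd.read_csv(path)
    required = {"label", "c0_M", "a480_t0", "a480_sup", "c_bp_M"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return [
        AggregationSample(
            c0=float(row.c0_M),
            a480_t0=float(row.a480_t0),
            a480_supernatant=float(row.a480_sup),
            c_bp=float(row.c_bp_M),
            label=str(row.label),
        )
        for row in df.itertuples()
    ]


def aggregation_report(samples: list[AggregationSample]) -> pd.DataFrame:
    """Per-sample aggregation quantities plus replicate mean ± standard error.

    Samples sharing a label are treated as replicates; the returned frame
    has one row per label with mean and standard error (n >= 1) of
    ``c_aggregate`` and the DOX/bp ratio.
    """
    rows = []
    for s in samples:
        agg = c_aggregate(s)
        rows.append(
            {
                "label": s.label,
                "c0_M": s.c0,
                "c_free_M": c_free_from_a480(s),
                "c_aggregate_M": agg,
                "dox_per_bp": dox_per_bp(agg, s.c_bp),
            }
        )
    df = pd.DataFrame(rows)

    def sem(x: pd.Series) -> float:
        x = x.dropna()
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    return (
        df.groupby("label", sort=False)
        .agg(
            n=("c_aggregate_M", "size"),
            c0_M=("c0_M", "mean"),
            c_aggregate_mean_M=("c_aggregate_M", "mean"),
            c_aggregate_sem_M=("c_aggregate_M", sem),
            dox_per_bp_mean=("dox_per_bp", "mean"),
            dox_per_bp_sem=("dox_per_bp", sem),
        )
        .reset_index()
    )


def solubility_molar(mg_per_ml: float, molar_mass: float = DOX_FREE_BASE_MW) -> float:
    """Convert a mass solubility (mg/ml) to molar units (M).

    With the free-base molar mass, the 0.3 mg/ml solubility of deprotonated
    DOX corresponds to ~0.55 mM.
    """
    if mg_per_ml < 0 or molar_mass <= 0:
        raise DomainError("solubility must be >= 0 and molar mass > 0")
    return mg_per_ml / molar_mass  # (mg/ml) / (g/mol) = (g/l) / (g/mol) = mol/l
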