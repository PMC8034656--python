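"""DON design registry and extinction/concentration calculus.

A DNA origami nanostructure (DON) is described for spectroscopic purposes by
two numbers: the count of hybridized nucleotides ``N_ds`` (each base pair
contributes two) and the count of unpaired nucleotides ``N_ss``.  These
drive the design-weighted per-nucleotide extinction coefficient at 260 nm

    eps260/nt = (6700 * N_ds + 10000 * N_ss) / (N_ds + N_ss)   [M^-1 cm^-1]

and the conversions between nucleotide, base-pair and whole-structure
concentrations (base pairs = N_ds / 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from doxorigami.errors import DomainError, ParseError, ValidationError

EPS_DS_PER_NT = 6700.0  # M^-1 cm^-1, hybridized nucleotide
EPS_SS_PER_NT = 10000.0  # M^-1 cm^-1, unpaired nucleotide


@dataclass(frozen=True)
class DonDesign:
    """Per-structure nucleotide bookkeeping.

    ``n_ds`` counts hybridized nucleotides (must be even: they pair
    two-by-two, so base pairs = ``n_ds / 2``); ``n_ss`` counts unpaired
    nucleotides.  ``scaffold_length_nt`` is informational only.
    """

    name: str
    n_ds: int
    n_ss: int
    scaffold_length_nt: int | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.n_ds < 0 or self.n_ss < 0:
            raise ValidationError(f"{self.name}: nucleotide counts must be >= 0")
        if self.n_ds + self.n_ss == 0:
            raise ValidationError(f"{self.name}: n_ds + n_ss must be > 0")
        if self.n_ds % 2 != 0:
            raise ValidationError(
                f"{self.name}: n_ds = {self.n_ds} is odd; hybridized nucleotides "
                "pair two-by-two"
            )

    @property
    def n_bp(self) -> int:
        """Number of base pairs, ``n_ds / 2``."""
        return self.n_ds // 2


def eps260_per_nt(design: DonDesign) -> float:
    """Design-weighted molar extinction coefficient per nucleotide at 260 nm.

    Weighted average of 6700 (hybridized) and 10000 (unpaired) M^-1 cm^-1;
    always in [6700, 10000].
    """
    total = design.n_ds + design.n_ss
    if total == 0:
        raise DomainError("design has no nucleotides")
    return (EPS_DS_PER_NT * design.n_ds + EPS_SS_PER_NT * design.n_ss) / total


def c_nt_from_a260(a260_dna: float, eps_per_nt: float, path_cm: float = 1.0) -> float:
    """Total nucleotide concentration from DOX-corrected A260 (Beer–Lambert).

    ``c(nt) = A260 / (eps * path)`` in M; ``a260_dna`` must already have the
    free-DOX 260 nm contribution subtracted.
    """
    if eps_per_nt <= 0 or path_cm <= 0:
        raise DomainError("extinction coefficient and path length must be > 0")
    if a260_dna < 0:
        raise DomainError(f"negative absorbance {a260_dna}")
    return a260_dna / (eps_per_nt * path_cm)


def c_bp_from_c_nt(c_nt: float, design: DonDesign) -> float:
    """Base-pair concentration from total nucleotide concentration.

    Only hybridized nucleotides count, two per base pair:
    ``c(bp) = 0.5 * c(nt) * N_ds / (N_ds + N_ss)``.
    """
    if c_nt < 0:
        raise DomainError(f"negative concentration {c_nt}")
    return 0.5 * c_nt * design.n_ds / (design.n_ds + design.n_ss)


def c_bp_from_don_concentration(c_don: float, design: DonDesign) -> float:
    """Base-pair concentration of a DON solution: ``c(bp) = c(DON) * N_ds / 2``."""
    if c_don < 0:
        raise DomainError(f"negative concentration {c_don}")
    return c_don * design.n_ds / 2.0


# The triangle is fully hybridized (no ssDNA regions): two 7249-nt scaffold
# equivalents of paired nucleotides.  The other designs' exact N_ds/N_ss are
# supplementary-derived placeholders, flagged editable via the registry file.
_DEFAULT_DESIGNS = [
    DonDesign("triangle", n_ds=14498, n_ss=0, scaffold_length_nt=7249),
    DonDesign(
        "bowtie", n_ds=14000, n_ss=498, scaffold_length_nt=7249,
        note="supplementary-derived placeholder, editable",
    ),
    DonDesign(
        "double-L", n_ds=14000, n_ss=498, scaffold_length_nt=7249,
        note="supplementary-derived placeholder, editable",
    ),
    DonDesign(
        "capsule", n_ds=15600, n_ss=528, scaffold_length_nt=8064,
        note="supplementary-derived placeholder, editable",
    ),
    DonDesign(
        "24HB", n_ds=14600, n_ss=520, scaffold_length_nt=7560,
        note="supplementary-derived placeholder, editable",
    ),
]


def default_registry() -> dict[str, DonDesign]:
    """Built-in design registry keyed by name."""
    return {d.name: d for d in _DEFAULT_DESIGNS}


def lookup_design(name: str, registry: dict[str, DonDesign] | None = None) -> DonDesign:
    """Retrieve a design by name; unknown names fail loudly."""
    registry = registry if registry is not None else default_registry()
    try:
        return registry[name]
    except KeyError:
        known = ", ".join(sorted(registry))
        raise KeyError(f"unknown design {name!r}; known designs: {known}") from None


def load_design_registry(path: str | Path) -> dict[str, DonDesign]:
    """Load a plain-text design registry.

    Format: records separated by blank lines, ``key = value`` pairs per
    record with keys ``name`` (required), ``n_ds``, ``n_ss``,
    ``scaffold_length_nt`` (optional), ``note`` (optional).  ``#`` starts a
    comment.  Validation errors name the offending record.
    """
    path = Path(path)
    registry: dict[str, DonDesign] = {}
    record: dict[str, str] = {}

    def flush(record: dict[str, str]) -> None:
        if not record:
            return
        name = record.get("name")
        if name is None:
            raise ParseError(f"{path}: record without a name: {record!r}")
        if name in registry:
            raise ParseError(f"{path}: duplicate design {name!r}")
        try:
            design = DonDesign(
                name=name,
                n_ds=int(record.get("n_ds", 0)),
                n_ss=int(record.get("n_ss", 0)),
                scaffold_length_nt=(
                    int(record["scaffold_length_nt"])
                    if "scaffold_length_nt" in record
                    else None
                ),
                note=record.get("note", ""),
            )
        except ValueError as exc:
            raise ParseError(f"{path}: record {name!r}: {exc}") from exc
        except ValidationError as exc:
            raise ValidationError(f"{path}: record {name!r}: {exc}") from exc
        registry[name] = design

    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                flush(record)
                record = {}
                continue
            if "=" not in line:
                raise ParseError(f"{path}: expected 'key = value', got {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            record[key] = value
    flush(record)
    if not registry:
        raise ParseError(f"{path}: no design records found")
    return registry


def write_design_registry(registry: dict[str, DonDesign], path: str | Path) -> None:
    """Write a registry in the format :func:`load_design_registry` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for design in registry.values():
            fh.write(f"name = {design.name}\n")
            fh.write(f"n_ds = {design.n_ds}\n")
            fh.write(f"n_ss = {design.n_ss}\n")
            if design.scaffold_length_nt is not None:
                fh.write(f"scaffold_length_nt = {design.scaffold_length_nt}\n")
            if design.note:
                fh.write(f"note = {design.note}\n")
            fh.write("\n")
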