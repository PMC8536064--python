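"""Per-peptide physicochemical descriptors.

The screening coordinates are length-normalised sums of per-residue scale
values: mean hydrophobicity and mean residue-pI.  Note that the "pI"
descriptor is deliberately the arithmetic mean of per-residue isoelectric
points — a map coordinate, NOT the Henderson–Hasselbalch isoelectric point
of the peptide.  Scales are data, not code: the package ships a default
hydropathy table (Kyte–Doolittle) and a free-amino-acid pI table, and every
operation takes the scale as an explicit argument so users can substitute
the exact tables their delivery-score surface was built with.

Masses and m/z use the standard monoisotopic / average residue tables via
pyteomics (unmodified residues, free termini, no Cys modification).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path
from typing import Literal, Mapping

from pyteomics import mass as _ptmass

from .library import STANDARD_AA, validate_peptide

#: Residue classes used throughout the composition analysis.
BASIC = frozenset("RK")
ACIDIC = frozenset("DE")
AROMATIC = frozenset("FYW")

PROTON_MASS = 1.00727646688  # Da


@dataclass(frozen=True)
class AAScale:
    """A named per-residue property table covering all 20 standard residues."""

    name: str
    values: Mapping[str, float]
    units: str = ""

    def __post_init__(self) -> None:
        missing = set(STANDARD_AA) - set(self.values)
        extra = set(self.values) - set(STANDARD_AA)
        if missing or extra:
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 standard "
                f"residues (missing {sorted(missing)}, extra {sorted(extra)})"
            )

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise KeyError(
                f"residue {residue!r} not in scale {self.name!r}"
            ) from None


def load_scale(path: str | Path) -> AAScale:
    """Load a two-column TSV scale file.

    The optional first comment line carries ``# scale: NAME\\tunits: U``;
    otherwise the file stem is used as the name.
    """
    path = Path(path)
    name, units = path.stem, ""
    values: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                for part in body.split("\t"):
                    if part.startswith("scale:"):
                        name = part.split(":", 1)[1].strip()
                    elif part.startswith("units:"):
                        units = part.split(":", 1)[1].strip()
                continue
            fields = line.split("\t")
            if fields[0] == "residue":
                continue
            values[fields[0]] = float(fields[1])
    return AAScale(name=name, values=values, units=units)


def default_hydrophobicity() -> AAScale:
    """The shipped default hydropathy scale (Kyte–Doolittle)."""
    return load_scale(files("pepscreen.data") / "hydrophobicity_kd.tsv")


def default_residue_pi() -> AAScale:
    """The shipped default per-residue pI table (free amino acids)."""
    return load_scale(files("pepscreen.data") / "residue_pi.tsv")


def mean_property(peptide: str, scale: AAScale) -> float:
    """Arithmetic mean of the scale values over the peptide's residues."""
    seq = validate_peptide(peptide)
    return sum(scale[r] for r in seq) / len(seq)


def molecular_mass(peptide: str, kind: Literal["mono", "average"] = "mono") -> float:
    """Neutral peptide mass in Da (residue masses + one water, free termini)."""
    seq = validate_peptide(peptide)
    if kind not in ("mono", "average"):
        raise ValueError(f"kind must be 'mono' or 'average', got {kind!r}")
    return _ptmass.calculate_mass(sequence=seq, average=(kind == "average"))


def mz(peptide: str, charge: int, kind: Literal["mono", "average"] = "mono") -> float:
    """m/z of the [M + charge·H]^charge+ ion: (M + z·m_proton) / z."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    m = molecular_mass(peptide, kind)
    return (m + charge * PROTON_MASS) / charge


def class_counts(peptide: str) -> dict:
    """Residue-class and per-letter composition of a peptide.

    Classes follow the bile-acid-binding enrichment analysis: basic {R, K},
    acidic {D, E}, aromatic {F, Y, W}.
    """
    seq = validate_peptide(peptide)
    letters = {aa: seq.count(aa) for aa in STANDARD_AA}
    return {
        "basic": sum(letters[a] for a in BASIC),
        "acidic": sum(letters[a] for a in ACIDIC),
        "aromatic": sum(letters[a] for a in AROMATIC),
        "letters": letters,
    }


@dataclass(frozen=True)
class DescriptorVector:
    peptide: str
    mean_hydrophobicity: float
    mean_pi: float
    mono_mass: float
    avg_mass: float
    basic: int
    acidic: int
    aromatic: int


def describe(peptide: str, hydro_scale: AAScale, pi_scale: AAScale) -> DescriptorVector:
    """Compute the full descriptor vector for one peptide."""
    cc = class_counts(peptide)
    return DescriptorVector(
        peptide=validate_peptide(peptide),
        mean_hydrophobicity=mean_property(peptide, hydro_scale),
        mean_pi=mean_property(peptide, pi_scale),
        mono_mass=molecular_mass(peptide, "mono"),
        avg_mass=molecular_mass(peptide, "average"),
        basic=cc["basic"],
        acidic=cc["acidic"],
        aromatic=cc["aromatic"],
    )
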