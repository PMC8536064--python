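"""Amino-acid-class enrichment statistics for screened peptide libraries.

Given predicted positive/negative labels over a library, peptides are
cross-tabulated by presence of a residue class (basic {R, K}, acidic
{D, E}, aromatic {F, Y, W}) and the association with positivity is
summarised as an odds ratio.  Both orientations are explicit: the
present-vs-absent odds ratio answers "how much do the odds of positivity
rise when the class is present", and absent-vs-present is its reciprocal
(the published acidic-class enrichment is conventionally reported in the
absent orientation, where lacking acidic residues strongly favours
positivity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .descriptors import class_counts


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = present & positive, b = present & negative,
    c = absent & positive, d = absent & negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class OddsRatioResult:
    value: float
    orientation: str
    corrected: bool  # True when the Haldane–Anscombe +0.5 was applied

    def rounded(self, sig: int = 3) -> float:
        return round_sig(self.value, sig)


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def contingency_by_class(
    peptides: Sequence[str],
    labels: Sequence[int],
    class_residues: Iterable[str],
) -> ContingencyTable2x2:
    """Cross-tabulate class presence (>= 1 residue anywhere) vs label."""
    residues = frozenset(class_residues)
    if not residues:
        raise ValueError("class_residues must be non-empty")
    if len(peptides) != len(labels):
        raise ValueError("peptides and labels must have equal length")
    a = b = c = d = 0
    for pep, lab in zip(peptides, labels):
        if lab not in (0, 1):
            raise ValueError(f"labels must be binary, got {lab!r}")
        present = any(r in residues for r in pep)
        if present and lab:
            a += 1
        elif present:
            b += 1
        elif lab:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)


def odds_ratio(
    table: ContingencyTable2x2,
    orientation: str = "present_vs_absent",
) -> OddsRatioResult:
    """Cross-product odds ratio (a·d)/(b·c), or its reciprocal.

    Zero cells are handled with the Haldane–Anscombe correction (+0.5 to
    every cell) and the result is flagged as corrected.
    """
    if orientation not in ("present_vs_absent", "absent_vs_present"):
        raise ValueError(f"unknown orientation {orientation!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    value = (a * d) / (b * c)
    if orientation == "absent_vs_present":
        value = 1.0 / value
    return OddsRatioResult(value=value, orientation=orientation, corrected=corrected)


@dataclass(frozen=True)
class PositiveRatio:
    n_pos: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_pos / self.n_total

    @property
    def percent(self) -> int:
        return round(100.0 * self.fraction)


def positive_ratio(n_pos: int, n_total: int) -> PositiveRatio:
    """Raw fraction and nearest-percent positive ratio of a library."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_pos <= n_total:
        raise ValueError("n_pos must lie in [0, n_total]")
    return PositiveRatio(n_pos=n_pos, n_total=n_total)


#: Ready-made subset filters for the probability-vs-score relation.
def min_class_filter(cls: str, minimum: int) -> Callable[[str], bool]:
    return lambda pep: class_counts(pep)[cls] >= minimum


DEFAULT_FILTERS: Mapping[str, Callable[[str], bool]] = {
    "acidic_ge2": min_class_filter("acidic", 2),
    "acidic_ge2_aromatic_ge2": lambda p: (
        class_counts(p)["acidic"] >= 2 and class_counts(p)["aromatic"] >= 2
    ),
}


def score_probability_relation(
    results: pd.DataFrame,
    filters: Mapping[str, Callable[[str], bool]] | None = None,
) -> dict:
    """Least-squares relation between model probability and delivery score.

    ``results`` must carry ``peptide``, ``probability`` and
    ``delivery_score`` columns.  Returns the regression of delivery score
    on probability (slope, intercept, Pearson r, n) plus, for each named
    subset filter, the subset size and mean probability / mean score (None
    when the subset is empty).  The default filters reproduce the two
    composition subsets of interest: >= 2 acidic residues, and >= 2 acidic
    plus >= 2 aromatic residues.
    """
    if filters is None:
        filters = DEFAULT_FILTERS
    n = len(results)
    if n < 3:
        raise ValueError(f"need >= 3 points for the regression, got {n}")
    x = results["probability"].to_numpy(dtype=float)
    y = results["delivery_score"].to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    out = {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "pearson_r": float(fit.rvalue),
        "n": n,
        "subsets": {},
    }
    for name, pred in filters.items():
        mask = results["peptide"].map(pred).to_numpy(dtype=bool)
        k = int(mask.sum())
        out["subsets"][name] = {
            "n": k,
            "mean_probability": float(np.mean(x[mask])) if k else None,
            "mean_delivery_score": float(np.mean(y[mask])) if k else None,
        }
    return out
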