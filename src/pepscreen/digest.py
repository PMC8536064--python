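"""Declarative protease cleavage engine and intact-release analysis.

Cleavage specificity is data, not code: a rule set names the residues the
enzyme cuts N-terminal to (the P1' targets) plus blocking rules — context
predicates over the positions flanking the scissile bond (P2, P1, P1',
P2') that veto a cut.  Bond i is the peptide bond between residues i and
i+1 (1-based), so P1 = residue i and P1' = residue i+1.

The shipped default is an approximation of the PeptideCutter thermolysin
table: cleavage N-terminal to A/F/I/L/M/V, vetoed when P2' is proline or
P1 is acidic (D/E).  Digestion is complete (all predicted bonds cut); a
subsequence is "released intact" when both its flanking bonds are cut or
at a protein terminus and no cut falls inside it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path
from typing import Sequence

from .library import STANDARD_AA, validate_peptide

_CONTEXT_OFFSETS = {"P2": -1, "P1": 0, "P1prime": 1, "P2prime": 2}


@dataclass(frozen=True)
class BlockingRule:
    """Veto a cut when the residue at ``position`` is in ``residues``.

    If the context position falls outside the sequence the rule does not
    apply (nothing to match).
    """

    position: str
    residues: frozenset[str]
    note: str = ""

    def __post_init__(self) -> None:
        if self.position not in _CONTEXT_OFFSETS:
            raise ValueError(
                f"unknown context position {self.position!r}; "
                f"expected one of {sorted(_CONTEXT_OFFSETS)}"
            )
        bad = self.residues - set(STANDARD_AA)
        if bad:
            raise ValueError(f"unknown residue letters in blocking rule: {sorted(bad)}")

    def blocks(self, sequence: str, bond: int) -> bool:
        # bond i joins residues i and i+1 (1-based); P1 is residue i.
        idx = bond + _CONTEXT_OFFSETS[self.position] - 1
        if not 0 <= idx < len(sequence):
            return False
        return sequence[idx] in self.residues


@dataclass(frozen=True)
class CleavageRuleSet:
    enzyme: str
    p1_prime_targets: frozenset[str]
    blocking_rules: tuple[BlockingRule, ...] = ()
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.p1_prime_targets:
            raise ValueError("p1_prime_targets must be non-empty")
        bad = self.p1_prime_targets - set(STANDARD_AA)
        if bad:
            raise ValueError(f"unknown residue letters in targets: {sorted(bad)}")


def load_rules(path: str | Path) -> CleavageRuleSet:
    """Load a JSON cleavage rule file."""
    with open(path) as fh:
        cfg = json.load(fh)
    blocks = tuple(
        BlockingRule(
            position=b["position"],
            residues=frozenset(b["residues"]),
            note=b.get("note", ""),
        )
        for b in cfg.get("blocking_rules", [])
    )
    return CleavageRuleSet(
        enzyme=cfg["enzyme"],
        p1_prime_targets=frozenset(cfg["p1_prime_targets"]),
        blocking_rules=blocks,
        provenance=cfg.get("provenance", ""),
    )


def save_rules(rules: CleavageRuleSet, path: str | Path) -> None:
    cfg = {
        "enzyme": rules.enzyme,
        "p1_prime_targets": "".join(sorted(rules.p1_prime_targets)),
        "blocking_rules": [
            {"position": b.position, "residues": "".join(sorted(b.residues)), "note": b.note}
            for b in rules.blocking_rules
        ],
        "provenance": rules.provenance,
    }
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=1)
        fh.write("\n")


def default_thermolysin() -> CleavageRuleSet:
    """The shipped thermolysin approximation (see module docstring)."""
    return load_rules(files("pepscreen.data") / "thermolysin.json")


def cut_sites(sequence: str, rules: CleavageRuleSet) -> list[int]:
    """All bonds cut by the enzyme, ascending.

    Bond i (1 <= i <= L-1) is cut when residue i+1 is a P1' target and no
    blocking rule vetoes it.
    """
    seq = validate_peptide(sequence)
    sites = []
    for bond in range(1, len(seq)):
        if seq[bond] not in rules.p1_prime_targets:
            continue
        if any(b.blocks(seq, bond) for b in rules.blocking_rules):
            continue
        sites.append(bond)
    return sites


@dataclass(frozen=True)
class DigestResult:
    cut_bonds: tuple[int, ...]
    fragments: tuple[tuple[int, int, str], ...]  # (start, end, sequence), 1-based


def digest(sequence: str, rules: CleavageRuleSet) -> DigestResult:
    """Complete digestion: fragments between consecutive cut bonds."""
    seq = validate_peptide(sequence)
    bonds = cut_sites(seq, rules)
    boundaries = [0] + bonds + [len(seq)]
    fragments = tuple(
        (lo + 1, hi, seq[lo:hi]) for lo, hi in zip(boundaries[:-1], boundaries[1:])
    )
    return DigestResult(cut_bonds=tuple(bonds), fragments=fragments)


def is_released_intact(
    sequence: str, start: int, end: int, rules: CleavageRuleSet
) -> tuple[bool, str]:
    """Can the span [start, end] be excised as one intact peptide?

    True iff the N-flanking bond (start-1) is cut or start is the protein
    N-terminus, the C-flanking bond (end) is cut or end is the C-terminus,
    and no cut bond lies strictly inside the span.  The reason string
    names the first failing condition.
    """
    seq = validate_peptide(sequence)
    if not (1 <= start <= end <= len(seq)):
        raise ValueError(
            f"span {start}_{end} out of range for length-{len(seq)} sequence"
        )
    sites = set(cut_sites(seq, rules))
    if any(start <= bond < end for bond in sites):
        return False, "internal cleavage"
    if start != 1 and (start - 1) not in sites:
        return False, "no cleavage at N-terminal flank"
    if end != len(seq) and end not in sites:
        return False, "no cleavage at C-terminal flank"
    return True, "released intact"


def minimal_releasable_superpeptide(
    sequence: str,
    start: int,
    end: int,
    rules: CleavageRuleSet,
    max_extension: int = 2,
) -> tuple[int, int] | None:
    """Shortest releasable span containing [start, end], or None.

    Searches spans extending the query by at most ``max_extension`` total
    residues, shortest first, ties broken by smallest start.  This is the
    operation behind rescuing a candidate peptide that cannot itself be
    excised by the enzyme: one terminal residue more may align both ends
    with cut sites.
    """
    seq = validate_peptide(sequence)
    if not (1 <= start <= end <= len(seq)):
        raise ValueError(
            f"span {start}_{end} out of range for length-{len(seq)} sequence"
        )
    if max_extension < 0:
        raise ValueError("max_extension must be >= 0")
    for extra in range(max_extension + 1):
        # extra residues added in total, split between the two ends
        for left in range(extra, -1, -1):  # larger left => smaller start first
            right = extra - left
            s, e = start - left, end + right
            if s < 1 or e > len(seq):
                continue
            ok, _ = is_released_intact(seq, s, e, rules)
            if ok:
                return (s, e)
    return None


def yield_estimate(
    protein_g_per_g_source: float,
    target_fraction: float,
    peptide_len: int,
    protein_len: int,
) -> tuple[float, float]:
    """Back-of-envelope purification yield per gram of source material.

    protein_mg = 1000 · grams of extracted protein · fraction that is the
    target protein; peptide_mg scales that by residue-count proportion
    peptide_len / protein_len (the peptide is one sub-span of the parent,
    counted by residues, exactly as the screening arithmetic does it).
    """
    if protein_g_per_g_source <= 0:
        raise ValueError("protein_g_per_g_source must be positive")
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    if peptide_len <= 0 or protein_len <= 0:
        raise ValueError("lengths must be positive")
    if peptide_len > protein_len:
        raise ValueError("peptide_len cannot exceed protein_len")
    protein_mg = 1000.0 * protein_g_per_g_source * target_fraction
    peptide_mg = protein_mg * peptide_len / protein_len
    return protein_mg, peptide_mg
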