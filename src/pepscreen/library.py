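"""Exhaustive k-mer peptide library construction from protein FASTA.

Proteins are cut into every overlapping window of length k (one-residue
shift from the N-terminus) for each requested k.  Windows that share a
sequence are merged into a single "independent peptide" whose provenance
lists every (protein, start, end) occurrence.  Positions are 1-based and
inclusive on both ends, always relative to the input FASTA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)


class EmptyInputError(ValueError):
    """Raised when an input file yields zero usable records."""


@dataclass(frozen=True)
class ProteinRecord:
    """A validated protein sequence over the 20 standard residues."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _STANDARD_SET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: non-standard residues {sorted(bad)}"
            )


@dataclass
class PeptideRecord:
    """A deduplicated k-mer with full positional provenance.

    ``provenance`` holds every (protein_id, start, end) occurrence, with
    1-based inclusive coordinates, so ``end - start + 1 == k``.
    """

    sequence: str
    provenance: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.sequence)

    @property
    def n_occurrences(self) -> int:
        return len(self.provenance)


def validate_peptide(sequence: str) -> str:
    """Uppercase and check a peptide against the standard alphabet."""
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty peptide sequence")
    bad = set(seq) - _STANDARD_SET
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)} in {sequence!r}")
    return seq


def read_fasta(path: str | Path) -> tuple[list[ProteinRecord], int]:
    """Read protein FASTA, dropping records with non-standard residues.

    Sequences are uppercased; whole records containing any residue outside
    the 20-letter alphabet (B, J, O, U, X, Z, ``*``, gaps, ...) are dropped
    with a logged warning — partial windows would corrupt positional
    provenance downstream.

    Returns
    -------
    (records, n_dropped)

    Raises
    ------
    EmptyInputError
        If the file contains no parseable FASTA entries at all.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    n_dropped = 0
    n_seen = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        n_seen += 1
        seq = str(entry.seq).upper()
        if not seq or set(seq) - _STANDARD_SET:
            n_dropped += 1
            log.warning(
                "dropping record %r: non-standard residues %s",
                entry.id,
                sorted(set(seq) - _STANDARD_SET),
            )
            continue
        records.append(
            ProteinRecord(id=entry.id, sequence=seq, description=entry.description)
        )
    if n_seen == 0:
        raise EmptyInputError(f"empty input: no FASTA records in {path}")
    return records, n_dropped


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write proteins as unwrapped FASTA (deterministic byte layout)."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else rec.description
            fh.write(f">{header}\n{rec.sequence}\n")


def slice_peptides(
    proteins: Sequence[ProteinRecord], k_values: Iterable[int]
) -> list[PeptideRecord]:
    """Produce the deduplicated one-residue-shift k-mer library.

    For each protein of length L and each k <= L all ``L - k + 1`` windows
    are emitted; windows sharing a sequence collapse into one record whose
    provenance lists every occurrence, in input order.  The library is
    sorted by (k, sequence) so output order is reproducible.
    """
    ks = sorted(set(k_values))
    if not ks:
        raise ValueError("k_values must be non-empty")
    if any(k < 1 for k in ks):
        raise ValueError(f"k values must be positive, got {ks}")

    by_seq: dict[str, PeptideRecord] = {}
    for prot in proteins:
        L = len(prot.sequence)
        for k in ks:
            for start in range(1, L - k + 2):
                seq = prot.sequence[start - 1 : start - 1 + k]
                rec = by_seq.get(seq)
                if rec is None:
                    rec = by_seq[seq] = PeptideRecord(sequence=seq)
                rec.provenance.append((prot.id, start, start + k - 1))
    return sorted(by_seq.values(), key=lambda r: (r.k, r.sequence))


def window_count(protein_length: int, k: int) -> int:
    """Pre-dedup window count for one protein and one k: max(0, L - k + 1)."""
    return max(0, protein_length - k + 1)


def library_to_frame(library: Sequence[PeptideRecord]) -> pd.DataFrame:
    """Tabulate a library: peptide, k, n_occurrences, provenance string."""
    rows = [
        {
            "peptide": rec.sequence,
            "k": rec.k,
            "n_occurrences": rec.n_occurrences,
            "provenance": ";".join(
                f"{pid}:{s}_{e}" for pid, s, e in rec.provenance
            ),
        }
        for rec in library
    ]
    return pd.DataFrame(rows, columns=["peptide", "k", "n_occurrences", "provenance"])


def write_library(library: Sequence[PeptideRecord], path: str | Path) -> None:
    library_to_frame(library).to_csv(path, sep="\t", index=False)


def read_library(path: str | Path) -> list[PeptideRecord]:
    """Read a library TSV written by :func:`write_library`."""
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "provenance": str})
    out: list[PeptideRecord] = []
    for row in df.itertuples(index=False):
        prov: list[tuple[str, int, int]] = []
        if isinstance(row.provenance, str) and row.provenance:
            for term in row.provenance.split(";"):
                pid, span = term.rsplit(":", 1)
                s, e = span.split("_")
                prov.append((pid, int(s), int(e)))
        out.append(PeptideRecord(sequence=validate_peptide(row.peptide), provenance=prov))
    return out


def library_totals(library: Sequence[PeptideRecord]) -> dict:
    """Per-k and joint independent-peptide counts for a library.

    Dedup keys on sequence alone; distinct k classes cannot collide, so the
    joint total equals the sum over k, but both are reported for audit.
    """
    per_k: dict[int, int] = {}
    for rec in library:
        per_k[rec.k] = per_k.get(rec.k, 0) + 1
    return {"per_k": per_k, "joint": len(library)}
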