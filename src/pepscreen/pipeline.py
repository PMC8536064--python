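"""End-to-end two-stage screening pipeline.

FASTA proteins → exhaustive k-mer library → descriptor coordinates →
probability model (first screen, probability > t1) → delivery-score
surface (second screen, score > t2) → candidate report with provenance.

Outputs are fully deterministic given a fixed model and inputs: the audit
table is sorted by (k, peptide) and the candidate report by delivery
score descending with lexicographic tie-breaks, so re-runs are
byte-identical and diffable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classifier import ProbModel
from .delivery import DeliveryScoreSurface, delivery_score, render_map
from .descriptors import AAScale, mean_property
from .library import (
    PeptideRecord,
    ProteinRecord,
    library_totals,
    slice_peptides,
    window_count,
)

log = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "peptide", "k", "probability", "mean_hydrophobicity", "mean_pi",
    "delivery_score", "passed_first", "passed_second", "n_occurrences",
    "provenance",
]


@dataclass
class PipelineResult:
    results: pd.DataFrame          # one row per independent peptide
    candidates: pd.DataFrame       # finalists: Peptide / Protein / Position
    stage_summary: dict
    library: list[PeptideRecord]


def _check_scale_match(surface: DeliveryScoreSurface, hydro: AAScale, pi: AAScale) -> None:
    # A surface built on different descriptor scales would silently shift
    # every coordinate, invalidating the threshold.
    if surface.hydro_scale is not None and surface.hydro_scale != hydro.name:
        raise ValueError(
            f"surface was built with hydrophobicity scale "
            f"{surface.hydro_scale!r} but descriptors use {hydro.name!r}"
        )
    if surface.pi_scale is not None and surface.pi_scale != pi.name:
        raise ValueError(
            f"surface was built with pI scale {surface.pi_scale!r} "
            f"but descriptors use {pi.name!r}"
        )


def _descriptor_summary(df: pd.DataFrame) -> dict:
    out = {}
    for k, grp in df.groupby("k"):
        before = grp
        after = grp[grp["passed_first"]]
        out[int(k)] = {
            "before": {
                "n": int(len(before)),
                "mean_pi": float(before["mean_pi"].mean()),
                "sd_pi": float(before["mean_pi"].std(ddof=1)) if len(before) > 1 else None,
                "mean_hydrophobicity": float(before["mean_hydrophobicity"].mean()),
                "sd_hydrophobicity": float(before["mean_hydrophobicity"].std(ddof=1))
                if len(before) > 1 else None,
            },
            "after": {
                "n": int(len(after)),
                "mean_pi": float(after["mean_pi"].mean()) if len(after) else None,
                "sd_pi": float(after["mean_pi"].std(ddof=1)) if len(after) > 1 else None,
                "mean_hydrophobicity": float(after["mean_hydrophobicity"].mean())
                if len(after) else None,
                "sd_hydrophobicity": float(after["mean_hydrophobicity"].std(ddof=1))
                if len(after) > 1 else None,
            },
        }
    return out


def run_pipeline(
    proteins: Sequence[ProteinRecord],
    model: ProbModel,
    surface: DeliveryScoreSurface,
    hydro_scale: AAScale,
    pi_scale: AAScale,
    k_values: Iterable[int] = (4, 5, 6, 7),
    first_threshold: float = 0.5,
    second_threshold: float = 50.0,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full two-stage screen and return the audit tables.

    The result table carries every independent peptide with its
    probability, descriptor coordinates, delivery score (computed only for
    first-screen survivors; NaN otherwise), per-stage pass flags and full
    provenance.  The candidate report mirrors the published reporting
    shape: Peptide, parent Protein, Position (1-based, relative to the
    input FASTA).
    """
    _check_scale_match(surface, hydro_scale, pi_scale)
    ks = sorted(set(k_values))

    if not proteins:
        results = pd.DataFrame(columns=RESULT_COLUMNS)
        candidates = pd.DataFrame(columns=["peptide", "protein", "position", "delivery_score"])
        summary = {
            "n_proteins": 0,
            "pre_dedup_windows": 0,
            "library_per_k": {},
            "library_total_joint": 0,
            "first_screen_survivors": 0,
            "finalists": 0,
            "thresholds": {"first": first_threshold, "second": second_threshold},
            "descriptor_summary": {},
        }
        if out_dir is not None:
            _write_outputs(results, candidates, summary, surface, ks, Path(out_dir))
        return PipelineResult(results, candidates, summary, [])

    library = slice_peptides(proteins, ks)
    pre_dedup = sum(window_count(len(p.sequence), k) for p in proteins for k in ks)

    seqs = [rec.sequence for rec in library]
    probs = np.asarray(model.predict_proba(seqs), dtype=float)
    hydro = np.array([mean_property(s, hydro_scale) for s in seqs])
    pi = np.array([mean_property(s, pi_scale) for s in seqs])
    passed_first = probs > first_threshold

    scores = np.full(len(seqs), np.nan)
    if passed_first.any():
        scores[passed_first] = delivery_score(
            surface, hydro[passed_first], pi[passed_first]
        )
    passed_second = passed_first & (scores > second_threshold)

    results = pd.DataFrame(
        {
            "peptide": seqs,
            "k": [rec.k for rec in library],
            "probability": probs,
            "mean_hydrophobicity": hydro,
            "mean_pi": pi,
            "delivery_score": scores,
            "passed_first": passed_first,
            "passed_second": passed_second,
            "n_occurrences": [rec.n_occurrences for rec in library],
            "provenance": [
                ";".join(f"{pid}:{s}_{e}" for pid, s, e in rec.provenance)
                for rec in library
            ],
        }
    ).sort_values(["k", "peptide"], kind="mergesort").reset_index(drop=True)

    # candidate report: one row per (finalist, provenance entry)
    rows = []
    for rec, prob, sc, ok in zip(library, probs, scores, passed_second):
        if not ok:
            continue
        for pid, s, e in rec.provenance:
            rows.append(
                {
                    "peptide": rec.sequence,
                    "protein": pid,
                    "position": f"{s}_{e}",
                    "probability": prob,
                    "delivery_score": sc,
                }
            )
    candidates = pd.DataFrame(
        rows, columns=["peptide", "protein", "position", "probability", "delivery_score"]
    )
    if len(candidates):
        candidates = candidates.sort_values(
            ["delivery_score", "peptide", "protein", "position"],
            ascending=[False, True, True, True],
            kind="mergesort",
        ).reset_index(drop=True)

    totals = library_totals(library)
    summary = {
        "n_proteins": len(proteins),
        "pre_dedup_windows": pre_dedup,
        "library_per_k": {str(k): v for k, v in sorted(totals["per_k"].items())},
        "library_total_joint": totals["joint"],
        "first_screen_survivors": int(passed_first.sum()),
        "finalists": int(passed_second.sum()),
        "thresholds": {"first": first_threshold, "second": second_threshold},
        "descriptor_summary": _descriptor_summary(results),
    }
    log.info(
        "pipeline: %d proteins -> %d peptides -> %d first-screen -> %d finalists",
        len(proteins), totals["joint"], summary["first_screen_survivors"],
        summary["finalists"],
    )
    if out_dir is not None:
        _write_outputs(results, candidates, summary, surface, ks, Path(out_dir))
    return PipelineResult(results, candidates, summary, library)


def _write_outputs(
    results: pd.DataFrame,
    candidates: pd.DataFrame,
    summary: dict,
    surface: DeliveryScoreSurface,
    ks: Sequence[int],
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    results.to_csv(out_dir / "results.tsv", sep="\t", index=False, float_format="%.6g")
    candidates.to_csv(out_dir / "candidates.tsv", sep="\t", index=False, float_format="%.6g")
    with open(out_dir / "stage_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    maps_dir = out_dir / "maps"
    maps_dir.mkdir(exist_ok=True)
    for k in ks:
        sub = results[(results["k"] == k) & results["passed_first"]]
        render_map(surface, sub, k, maps_dir / f"map_{k}mer.png")
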