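"""Synthetic fixtures for every pipeline stage.

The generators stand in for data the screen needs but which is external
prior work: an edible-protein FASTA, a labelled bile-acid-binding peptide
set, a silica delivery-score surface, and dose-response assay tables.
They emulate the statistical *structure* of the real inputs — amino-acid
composition, class-presence label biases of the published enrichment
magnitudes (basic raises positivity odds roughly 6.5-fold, acidic
suppresses them, aromatic raises them modestly), a smooth score surface
favouring hydrophobic/low-pI peptides, and noisy sigmoid dose-response
curves — not real sequence biology (no domains, repeats, or homology).

Every generator is a pure function of (config, arguments): the same seed
yields byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .delivery import DeliveryScoreSurface, save_surface
from .descriptors import ACIDIC, AROMATIC, BASIC
from .library import STANDARD_AA, ProteinRecord, write_fasta

#: Average amino-acid frequencies of well-annotated proteins (UniProt-like),
#: normalised; used as the default residue composition.
DEFAULT_COMPOSITION: Mapping[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic study conditions.

    The label model is logistic in residue-class *presence* indicators
    (presence/absence is what the enrichment analysis tabulates); the
    default weights are the natural logs of the published enrichment
    magnitudes, and the intercept puts the positive rate near the
    one-third observed for real libraries.
    """

    seed: int
    # protein set
    n_proteins: int = 200
    min_length: int = 60
    max_length: int = 300
    composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    # label model (class-presence logistic)
    label_intercept: float = -1.2
    basic_weight: float = math.log(6.5)
    acidic_weight: float = -math.log(22.0)
    aromatic_weight: float = math.log(2.5)
    # delivery-score surface
    hydro_range: tuple[float, float] = (-4.5, 4.5)
    pi_range: tuple[float, float] = (2.5, 11.0)
    n_grid: int = 25
    hydro_gain: float = 1.2
    pi_gain: float = 1.0
    hydro_mid: float = 0.5
    pi_mid: float = 5.5
    # dose-response truth
    dr_bottom: float = 0.0
    dr_top: float = 100.0
    dr_dc50: float = 3.0
    dr_slope: float = 2.0
    dr_noise_sd: float = 5.0
    dr_cmin: float = 0.3
    dr_cmax: float = 10.0

    def __post_init__(self) -> None:
        weights = np.array(
            [self.label_intercept, self.basic_weight, self.acidic_weight,
             self.aromatic_weight]
        )
        if not np.all(np.isfinite(weights)):
            raise ValueError("label-model weights must be finite")
        if self.dr_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        comp = np.array([self.composition[a] for a in STANDARD_AA])
        if np.any(comp < 0) or comp.sum() <= 0:
            raise ValueError("composition weights must be non-negative, not all zero")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def _composition_probs(config: SyntheticConfig) -> np.ndarray:
    p = np.array([config.composition.get(a, 0.0) for a in STANDARD_AA], dtype=float)
    return p / p.sum()


def _sample_sequence(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    letters = rng.choice(list(STANDARD_AA), size=length, p=probs)
    return "".join(letters)


def gen_proteins(
    config: SyntheticConfig, path: str | Path | None = None
) -> list[ProteinRecord]:
    """I.i.d.-residue proteins with uniformly drawn lengths; seeded.

    If ``path`` is given the set is also written as FASTA (byte-identical
    across runs with the same config).
    """
    rng = np.random.default_rng(config.seed)
    probs = _composition_probs(config)
    records = []
    width = len(str(config.n_proteins))
    for i in range(config.n_proteins):
        length = int(rng.integers(config.min_length, config.max_length + 1))
        seq = _sample_sequence(rng, length, probs)
        records.append(
            ProteinRecord(id=f"synthetic_{i + 1:0{width}d}", sequence=seq,
                          description=f"synthetic_{i + 1:0{width}d} synthetic edible protein")
        )
    if path is not None:
        write_fasta(records, path)
    return records


def label_probability(config: SyntheticConfig, peptide: str) -> float:
    """The logistic class-presence model used to draw labels."""
    has_basic = any(r in BASIC for r in peptide)
    has_acidic = any(r in ACIDIC for r in peptide)
    has_aromatic = any(r in AROMATIC for r in peptide)
    z = (
        config.label_intercept
        + config.basic_weight * has_basic
        + config.acidic_weight * has_acidic
        + config.aromatic_weight * has_aromatic
    )
    return float(expit(z))


def gen_labeled_peptides(
    config: SyntheticConfig, n: int, k: int, path: str | Path | None = None
) -> pd.DataFrame:
    """Random k-mers with Bernoulli labels from the class-presence model."""
    rng = np.random.default_rng(config.seed)
    probs = _composition_probs(config)
    seqs = ["".join(row) for row in rng.choice(list(STANDARD_AA), size=(n, k), p=probs)]
    p = np.array([label_probability(config, s) for s in seqs])
    labels = (rng.random(n) < p).astype(int)
    df = pd.DataFrame({"sequence": seqs, "label": labels})
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def gen_surface(
    config: SyntheticConfig, path: str | Path | None = None
) -> DeliveryScoreSurface:
    """Smooth logistic-ridge surface, high at high hydrophobicity / low pI.

    score(h, p) = 100 · expit(hydro_gain·(h − hydro_mid) − pi_gain·(p −
    pi_mid)); values lie in [0, 100] and are monotone along each axis when
    the gains are positive.
    """
    h_axis = np.linspace(*config.hydro_range, config.n_grid)
    p_axis = np.linspace(*config.pi_range, config.n_grid)
    H, P = np.meshgrid(h_axis, p_axis, indexing="ij")
    z = config.hydro_gain * (H - config.hydro_mid) - config.pi_gain * (P - config.pi_mid)
    surface = DeliveryScoreSurface(
        hydro_axis=h_axis,
        pi_axis=p_axis,
        scores=100.0 * expit(z),
        hydro_scale="kyte_doolittle",
        pi_scale="residue_pi",
    )
    if path is not None:
        save_surface(surface, path)
    return surface


def gen_dose_response(
    config: SyntheticConfig,
    n_points: int = 8,
    replicates: int = 3,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Noisy 4PL assay table: log-spaced concentrations, Gaussian noise.

    Responses are clipped to [0, 100] (the assay reports a percentage).
    """
    rng = np.random.default_rng(config.seed)
    conc = np.geomspace(config.dr_cmin, config.dr_cmax, n_points)
    rows = []
    for rep in range(1, replicates + 1):
        with np.errstate(divide="ignore"):
            truth = config.dr_bottom + (config.dr_top - config.dr_bottom) / (
                1.0 + (config.dr_dc50 / conc) ** config.dr_slope
            )
        noise = config.dr_noise_sd * rng.standard_normal(n_points)
        resp = np.clip(truth + noise, 0.0, 100.0)
        for c, r in zip(conc, resp):
            rows.append({"concentration": c, "response": r, "replicate": rep})
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def surrogate_from_label_model(config: SyntheticConfig):
    """The closed-form classifier matching the label-generating model."""
    from .classifier import SurrogateLogistic

    return SurrogateLogistic(
        intercept=config.label_intercept,
        basic_weight=config.basic_weight,
        acidic_weight=config.acidic_weight,
        aromatic_weight=config.aromatic_weight,
    )
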