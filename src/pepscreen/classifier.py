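"""First-screening stage: probability models of bile-acid-binding activity.

Two interchangeable model kinds are provided.  ``train_forest`` fits a
random forest on composition-derived features, re-creating the kind of
classifier used to label the edible-peptide library (the original model's
training set is not public, so the component is trainable rather than
fixed).  ``SurrogateLogistic`` is a closed-form logistic model over
residue-class presence indicators — deterministic, transparent, and
shaped like the enrichment structure the screen is known to exploit
(basic residues raise positivity odds, acidic residues lower them) — used
as a test double and for fully reproducible pipeline runs.

A peptide passes the first screen when its predicted probability is
STRICTLY greater than the threshold (default 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier

from .descriptors import AAScale, class_counts, mean_property, molecular_mass
from .library import STANDARD_AA, PeptideRecord, validate_peptide

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"count_{aa}" for aa in STANDARD_AA]
    + ["length", "mean_hydrophobicity", "mean_pi", "avg_mass", "basic", "acidic", "aromatic"]
)


@dataclass(frozen=True)
class LabeledPeptide:
    sequence: str
    label: int

    def __post_init__(self) -> None:
        validate_peptide(self.sequence)
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


def featurize(peptide: str, hydro_scale: AAScale, pi_scale: AAScale) -> np.ndarray:
    """Fixed-order composition feature vector (see FEATURE_NAMES)."""
    seq = validate_peptide(peptide)
    cc = class_counts(seq)
    letters = cc["letters"]
    vec = [float(letters[aa]) for aa in STANDARD_AA]
    vec += [
        float(len(seq)),
        mean_property(seq, hydro_scale),
        mean_property(seq, pi_scale),
        molecular_mass(seq, "average"),
        float(cc["basic"]),
        float(cc["acidic"]),
        float(cc["aromatic"]),
    ]
    return np.asarray(vec)


def featurize_many(
    peptides: Sequence[str], hydro_scale: AAScale, pi_scale: AAScale
) -> np.ndarray:
    return np.vstack([featurize(p, hydro_scale, pi_scale) for p in peptides])


class ProbModel(Protocol):
    """Anything that maps peptide sequences to probabilities in [0, 1]."""

    def predict_proba(self, peptides: Sequence[str]) -> np.ndarray: ...


@dataclass
class ForestModel:
    """A fitted random-forest probability model plus its feature spec."""

    forest: RandomForestClassifier
    hydro_scale: AAScale
    pi_scale: AAScale
    feature_spec: tuple[str, ...] = FEATURE_NAMES
    oob_accuracy: float | None = None

    def predict_proba(self, peptides: Sequence[str]) -> np.ndarray:
        X = featurize_many(peptides, self.hydro_scale, self.pi_scale)
        return self.forest.predict_proba(X)[:, 1]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ForestModel":
        return joblib.load(path)


def train_forest(
    data: Sequence[LabeledPeptide],
    hydro_scale: AAScale,
    pi_scale: AAScale,
    seed: int,
    n_estimators: int = 300,
    **forest_kwargs,
) -> ForestModel:
    """Fit a random forest on labeled peptides; reproducible given the seed.

    Hyperparameters default to the ecosystem's standard (hundreds of trees,
    sqrt(p) features per split); out-of-bag accuracy is recorded on the model.
    """
    labels = np.array([d.label for d in data])
    if len(set(labels.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    if len(data) < 10:
        warnings.warn(f"only {len(data)} training peptides; fit will be unstable")
    X = featurize_many([d.sequence for d in data], hydro_scale, pi_scale)
    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
        **forest_kwargs,
    )
    forest.fit(X, labels)
    return ForestModel(
        forest=forest,
        hydro_scale=hydro_scale,
        pi_scale=pi_scale,
        oob_accuracy=float(forest.oob_score_),
    )


@dataclass(frozen=True)
class SurrogateLogistic:
    """Closed-form logistic model over residue-class presence indicators.

    probability = expit(intercept + basic_w·[has basic] + acidic_w·[has
    acidic] + aromatic_w·[has aromatic]).
    """

    intercept: float = 0.0
    basic_weight: float = 0.0
    acidic_weight: float = 0.0
    aromatic_weight: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.intercept, self.basic_weight, self.acidic_weight, self.aromatic_weight):
            if not np.isfinite(v):
                raise ValueError("surrogate coefficients must be finite")

    def linear_score(self, peptide: str) -> float:
        cc = class_counts(peptide)
        return (
            self.intercept
            + self.basic_weight * (cc["basic"] > 0)
            + self.acidic_weight * (cc["acidic"] > 0)
            + self.aromatic_weight * (cc["aromatic"] > 0)
        )

    def predict_proba(self, peptides: Sequence[str]) -> np.ndarray:
        return expit(np.array([self.linear_score(p) for p in peptides]))


def first_screen(
    model: ProbModel,
    peptides: Sequence[PeptideRecord] | Sequence[str],
    threshold: float = 0.5,
) -> tuple[list, pd.DataFrame]:
    """Keep peptides whose predicted probability is strictly > threshold.

    Returns the surviving peptides (same objects as the input) and the full
    score table for audit.
    """
    seqs = [p.sequence if isinstance(p, PeptideRecord) else p for p in peptides]
    probs = np.asarray(model.predict_proba(seqs), dtype=float)
    passed = probs > threshold
    table = pd.DataFrame(
        {"peptide": seqs, "probability": probs, "passed": passed}
    )
    positives = [p for p, keep in zip(peptides, passed) if keep]
    return positives, table
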