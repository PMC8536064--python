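"""Second-screening stage: the intestinal-delivery score surface.

The delivery score quantifies how well a peptide adsorbed to heat-treated
porous silica at gastric pH is released at intestinal pH, as a function of
the peptide's (mean hydrophobicity, mean residue-pI) coordinates.  The
surface itself is empirical prior work and is supplied as data: a
rectangular grid over the two descriptor axes.  Queries are answered by
bilinear interpolation; coordinates outside the grid are clamped to the
nearest edge before interpolating (the surface's behaviour outside the
measured peptide range is unknown, so the nearest measured value is the
least-surprising extrapolation, and the choice is recorded in the surface
metadata).

A candidate passes the second screen when its delivery score is STRICTLY
greater than the threshold (default 50).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator


class SurfaceFormatError(ValueError):
    """Raised when a surface config fails validation."""


@dataclass
class DeliveryScoreSurface:
    """Delivery scores on a rectangular (hydrophobicity, pI) grid.

    ``scores[i, j]`` is the score at ``(hydro_axis[i], pi_axis[j])``.
    ``hydro_scale`` / ``pi_scale`` name the descriptor scales the grid was
    built with; screening refuses to mix a surface with descriptors
    computed on different scales.
    """

    hydro_axis: np.ndarray
    pi_axis: np.ndarray
    scores: np.ndarray
    hydro_scale: str | None = None
    pi_scale: str | None = None
    extrapolation: str = "clamp-to-edge"

    def __post_init__(self) -> None:
        self.hydro_axis = np.asarray(self.hydro_axis, dtype=float)
        self.pi_axis = np.asarray(self.pi_axis, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        for name, axis in (("hydro", self.hydro_axis), ("pi", self.pi_axis)):
            if axis.ndim != 1 or axis.size < 2:
                raise SurfaceFormatError(f"{name} axis must be 1-D with >= 2 values")
            diffs = np.diff(axis)
            if not np.all(diffs > 0):
                idx = int(np.argmin(diffs))
                raise SurfaceFormatError(
                    f"{name} axis not strictly increasing at index {idx}"
                )
        if self.scores.shape != (self.hydro_axis.size, self.pi_axis.size):
            raise SurfaceFormatError(
                f"score grid shape {self.scores.shape} does not match axes "
                f"({self.hydro_axis.size}, {self.pi_axis.size})"
            )
        if not np.all(np.isfinite(self.scores)):
            raise SurfaceFormatError("score grid contains non-finite values")
        self._interp = RegularGridInterpolator(
            (self.hydro_axis, self.pi_axis), self.scores, method="linear"
        )

    def __call__(self, hydro, pi):
        return delivery_score(self, hydro, pi)


def load_surface(path: str | Path) -> DeliveryScoreSurface:
    """Load and validate a JSON surface config.

    Expected keys: ``hydro_axis``, ``pi_axis``, ``scores`` (row i = hydro
    axis value i), optional ``hydro_scale`` / ``pi_scale`` names.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = json.load(fh)
    for key in ("hydro_axis", "pi_axis", "scores"):
        if key not in cfg:
            raise SurfaceFormatError(f"surface config missing key {key!r}")
    rows = cfg["scores"]
    ncols = {len(r) for r in rows}
    if len(ncols) > 1:
        ragged = next(i for i, r in enumerate(rows) if len(r) != len(rows[0]))
        raise SurfaceFormatError(f"ragged score grid at row {ragged}")
    return DeliveryScoreSurface(
        hydro_axis=cfg["hydro_axis"],
        pi_axis=cfg["pi_axis"],
        scores=rows,
        hydro_scale=cfg.get("hydro_scale"),
        pi_scale=cfg.get("pi_scale"),
    )


def save_surface(surface: DeliveryScoreSurface, path: str | Path) -> None:
    cfg = {
        "hydro_axis": surface.hydro_axis.tolist(),
        "pi_axis": surface.pi_axis.tolist(),
        "scores": surface.scores.tolist(),
        "hydro_scale": surface.hydro_scale,
        "pi_scale": surface.pi_scale,
        "extrapolation": surface.extrapolation,
    }
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=1)
        fh.write("\n")


def delivery_score(surface: DeliveryScoreSurface, hydro, pi):
    """Bilinear interpolation with clamp-to-edge outside the grid.

    Scalar in, scalar out; array in, array out.
    """
    h = np.asarray(hydro, dtype=float)
    p = np.asarray(pi, dtype=float)
    if not (np.all(np.isfinite(h)) and np.all(np.isfinite(p))):
        raise ValueError("coordinates must be finite")
    hc = np.clip(h, surface.hydro_axis[0], surface.hydro_axis[-1])
    pc = np.clip(p, surface.pi_axis[0], surface.pi_axis[-1])
    pts = np.stack([np.atleast_1d(hc), np.atleast_1d(pc)], axis=-1)
    out = surface._interp(pts)
    if h.ndim == 0:
        return float(out[0])
    return out


def second_screen(
    candidates: pd.DataFrame,
    surface: DeliveryScoreSurface,
    threshold: float = 50.0,
) -> pd.DataFrame:
    """Annotate candidates with delivery scores and keep those > threshold.

    ``candidates`` must carry ``mean_hydrophobicity`` and ``mean_pi``
    columns.  Returns the finalists with a ``delivery_score`` column.
    """
    required = {"mean_hydrophobicity", "mean_pi"}
    missing = required - set(candidates.columns)
    if missing:
        raise ValueError(f"candidates missing descriptor columns {sorted(missing)}")
    annotated = candidates.copy()
    if len(annotated):
        annotated["delivery_score"] = delivery_score(
            surface,
            annotated["mean_hydrophobicity"].to_numpy(),
            annotated["mean_pi"].to_numpy(),
        )
    else:
        annotated["delivery_score"] = np.array([], dtype=float)
    return annotated[annotated["delivery_score"] > threshold].reset_index(drop=True)


def render_map(
    surface: DeliveryScoreSurface,
    peptides: pd.DataFrame,
    k: int,
    path: str | Path,
) -> None:
    """Write a colour map: score surface as background, peptides as points.

    All plotted peptides must have length k (the maps are drawn per k-mer
    class); an empty table yields a background-only image.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(peptides) and not (peptides["peptide"].str.len() == k).all():
        raise ValueError(f"render_map: all peptides must have length {k}")
    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(
        surface.pi_axis,
        surface.hydro_axis,
        surface.scores,
        shading="gouraud",
        cmap="jet",
        vmin=0,
        vmax=100,
    )
    fig.colorbar(mesh, ax=ax, label="delivery score")
    if len(peptides):
        ax.scatter(
            peptides["mean_pi"],
            peptides["mean_hydrophobicity"],
            s=8,
            c="black",
            marker="o",
        )
    ax.set_xlabel("mean pI")
    ax.set_ylabel("mean hydrophobicity")
    ax.set_title(f"{k}-mer peptides")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
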