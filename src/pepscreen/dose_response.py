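"""Sigmoid dose-response fitting and DC50 estimation.

The micelle-disruption assay reports the percent decrease of micellar
cholesterol as a function of peptide concentration.  The dose dependency
is summarised by DC50 — the concentration producing a 50% cholesterol
decrease, i.e. the midpoint of the fitted sigmoid.  The model is the
four-parameter log-logistic curve

    response(c) = bottom + (top - bottom) / (1 + (dc50 / c) ** slope)

which nests the two-parameter case via the optional fixed asymptotes;
fixing top = 100 and bottom = 0 is the documented default for assay use,
since full disruption is observed at saturating concentrations.

Fitting is nonlinear least squares (scipy) with a small grid of
multi-starts built from the data quantiles, plus seeded jitter, with the
best residual sum of squares kept.  Non-convergence is reported on the
returned fit object, never as a silent bad number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class DoseResponseData:
    """Concentrations (mg/mL) with % cholesterol-decrease responses."""

    concentrations: np.ndarray
    responses: np.ndarray
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "concentrations", np.asarray(self.concentrations, dtype=float)
        )
        object.__setattr__(self, "responses", np.asarray(self.responses, dtype=float))
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must have equal length")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if np.unique(self.concentrations).size < 4:
            raise ValueError("need >= 4 distinct concentrations for fitting")

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "DoseResponseData":
        reps = df["replicate"].to_numpy() if "replicate" in df.columns else None
        return DoseResponseData(
            concentrations=df["concentration"].to_numpy(),
            responses=df["response"].to_numpy(),
            replicates=reps,
        )


@dataclass(frozen=True)
class DoseResponseFit:
    bottom: float
    top: float
    dc50: float
    slope: float
    rss: float
    converged: bool
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            if self.dc50 <= 0:
                raise ValueError("converged fit must have dc50 > 0")
            if self.bottom > self.top:
                raise ValueError("converged fit must have bottom <= top")

    def predict(self, c):
        return four_pl(np.asarray(c, dtype=float), self.bottom, self.top, self.dc50, self.slope)


def four_pl(c, bottom, top, dc50, slope):
    """Four-parameter log-logistic response curve."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(c > 0, dc50 / np.maximum(c, 1e-300), np.inf)
        return bottom + (top - bottom) / (1.0 + ratio**slope)


def fit_sigmoid(
    data: DoseResponseData,
    fix_bottom: float | None = None,
    fix_top: float | None = None,
    seed: int = 0,
    n_starts: int = 4,
) -> DoseResponseFit:
    """Least-squares 4PL fit with quantile-based seeded multi-start.

    ``fix_bottom`` / ``fix_top`` pin the asymptotes (e.g. 0 and 100 for a
    normalised assay).  The fit that minimises the residual sum of squares
    over all starts is returned; if no start converges the returned fit
    has ``converged=False`` and carries the solver's message.
    """
    c = data.concentrations
    y = data.responses
    if np.allclose(y, y[0]):
        raise ValueError("responses are all equal; no dose dependency to fit")

    pos = c[c > 0]
    rng = np.random.default_rng(seed)
    b0 = fix_bottom if fix_bottom is not None else float(np.min(y))
    t0 = fix_top if fix_top is not None else float(np.max(y))
    dc50_starts = np.quantile(pos, [0.25, 0.5, 0.75])
    slope_starts = np.array([0.5, 1.0, 2.0, 4.0])

    starts = []
    for d in dc50_starts:
        for s in slope_starts:
            starts.append((d, s))
    # a few seeded jittered starts guard against a pathological grid
    for _ in range(n_starts):
        d = float(np.exp(np.log(np.median(pos)) + 0.5 * rng.standard_normal()))
        s = float(np.exp(rng.uniform(np.log(0.3), np.log(6.0))))
        starts.append((d, s))

    free = [n for n, fx in (("bottom", fix_bottom), ("top", fix_top)) if fx is None]

    def model(cc, *params):
        it = iter(params)
        bottom = next(it) if "bottom" in free else fix_bottom
        top = next(it) if "top" in free else fix_top
        dc50, slope = next(it), next(it)
        return four_pl(cc, bottom, top, dc50, slope)

    best = None
    last_msg = ""
    for d0, s0 in starts:
        p0, lo, hi = [], [], []
        if "bottom" in free:
            p0.append(b0), lo.append(-np.inf), hi.append(np.inf)
        if "top" in free:
            p0.append(t0), lo.append(-np.inf), hi.append(np.inf)
        p0 += [d0, s0]
        lo += [1e-12, 1e-6]
        hi += [np.inf, np.inf]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    model, c, y, p0=p0, bounds=(lo, hi), maxfev=20000
                )
        except (RuntimeError, ValueError) as exc:
            last_msg = str(exc)
            continue
        rss = float(np.sum((model(c, *popt) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)

    if best is None:
        return DoseResponseFit(
            bottom=np.nan, top=np.nan, dc50=np.nan, slope=np.nan,
            rss=np.nan, converged=False, message=last_msg or "no start converged",
        )
    rss, popt = best
    it = iter(popt)
    bottom = float(next(it)) if "bottom" in free else float(fix_bottom)
    top = float(next(it)) if "top" in free else float(fix_top)
    dc50_v, slope_v = float(next(it)), float(next(it))
    if bottom > top:
        # exact mirror identity of the 4PL: swap asymptotes, negate slope
        bottom, top, slope_v = top, bottom, -slope_v
    return DoseResponseFit(
        bottom=bottom, top=top, dc50=dc50_v, slope=slope_v,
        rss=rss, converged=True,
    )


def dc50(fit: DoseResponseFit) -> float:
    """The fitted midpoint concentration (mg/mL) of a converged fit."""
    if not fit.converged:
        raise ValueError(f"fit did not converge: {fit.message}")
    return fit.dc50


def read_dose_response(path) -> DoseResponseData:
    """Read a TSV with columns concentration, response[, replicate]."""
    return DoseResponseData.from_frame(pd.read_csv(path, sep="\t"))
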