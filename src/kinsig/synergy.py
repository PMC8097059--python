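"""Dose–response fitting and Bliss-independence synergy scoring.

Viability curves are fitted with the four-parameter logistic (4PL)

    y(x) = bottom + (top − bottom) / (1 + (x / IC50)^hill)

by unweighted least squares on log10 dose, with multi-start initialization
from data quantiles.  Drug-pair interaction is scored against the Bliss
independence null: for surviving fractions S_A, S_B of the single agents
and S_AB of the combination,

    index = S_A · S_B − S_AB

so a positive index means the combination kills more than independence
predicts (synergy), negative means antagonism, and 0 an additive pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .io import DoseResponseTable

__all__ = [
    "DoseResponseFit",
    "fit_4pl",
    "four_pl",
    "BlissRecord",
    "bliss_index",
    "bliss_surface",
    "compare_ic50",
]


def four_pl(dose: np.ndarray, bottom: float, top: float, ic50: float,
            hill: float) -> np.ndarray:
    """Four-parameter logistic response at the given doses (same units as IC50)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    ic50: float                 # µM
    hill: float
    rss: float
    converged: bool
    n_points: int

    def predict(self, dose: np.ndarray) -> np.ndarray:
        return four_pl(dose, self.bottom, self.top, self.ic50, self.hill)


def _4pl_logdose(logx: np.ndarray, bottom: float, top: float,
                 log_ic50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logx - log_ic50)))


def fit_4pl(table: DoseResponseTable, min_range: float = 0.02) -> DoseResponseFit:
    """Least-squares 4PL fit of a dose–response table.

    Requires ≥4 distinct doses.  Fits on log10 dose with multi-start
    initialization (IC50 starts at the dose quantiles, hill at ±1); IC50 is
    bounded within 10^±4 of the observed dose range.  A response range
    below ``min_range`` raises ``"no dose dependence"``; non-convergence is
    flagged and no IC50 is reported.
    """
    doses = table.table["dose"].to_numpy(dtype=float)
    resp = table.table["response"].to_numpy(dtype=float)
    if not np.isfinite(resp).all():
        raise ValueError("responses must be finite")
    if len(np.unique(doses)) < 4:
        raise ValueError("4PL fitting requires at least 4 distinct doses")
    if np.ptp(resp) < min_range:
        raise ValueError("no dose dependence (response range below noise floor)")

    logx = np.log10(doses)
    lo, hi = logx.min() - 4.0, logx.max() + 4.0
    span = resp.max() - resp.min()
    bounds = (
        [resp.min() - span, resp.min() - span, lo, -50.0],
        [resp.max() + span, resp.max() + span, hi, 50.0],
    )

    best = None
    for q in (0.25, 0.5, 0.75):
        for hill0 in (1.0, -1.0):
            p0 = [resp.min(), resp.max(), float(np.quantile(logx, q)), hill0]
            try:
                popt, _ = curve_fit(_4pl_logdose, logx, resp, p0=p0,
                                    bounds=bounds, maxfev=20000)
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((resp - _4pl_logdose(logx, *popt)) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
    if best is None:
        return DoseResponseFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                               converged=False, n_points=len(resp))
    (b, t, log_ic50, hill), rss = best
    bottom, top = (b, t) if b <= t else (t, b)
    if not bottom < top:
        return DoseResponseFit(bottom, top, np.nan, hill, rss,
                               converged=False, n_points=len(resp))
    return DoseResponseFit(float(bottom), float(top), float(10.0 ** log_ic50),
                           float(hill), rss, converged=True, n_points=len(resp))


@dataclass
class BlissRecord:
    s_a: float
    s_b: float
    s_ab: float
    index: float

    @property
    def call(self) -> str:
        if self.index > 0:
            return "synergy"
        if self.index < 0:
            return "antagonism"
        return "additive"


def bliss_index(s_a: float, s_b: float, s_ab: float) -> BlissRecord:
    """Bliss independence index for one dose pair.

    Surviving fractions may slightly exceed 1 (up to 1.2) to tolerate assay
    noise; negative fractions are rejected.  index = S_A·S_B − S_AB, with
    positive = synergy.
    """
    for name, s in (("S_A", s_a), ("S_B", s_b), ("S_AB", s_ab)):
        if s < 0:
            raise ValueError(f"{name} is negative")
        if s > 1.2:
            raise ValueError(f"{name} = {s} exceeds the tolerated maximum 1.2")
    return BlissRecord(s_a, s_b, s_ab, s_a * s_b - s_ab)


def bliss_surface(
    single_a: DoseResponseTable,
    single_b: DoseResponseTable,
    combination: pd.DataFrame,
) -> pd.DataFrame:
    """Bliss index over a combination grid.

    ``combination`` has columns dose_a, dose_b, response.  Single-agent
    surviving fractions at each grid dose are the replicate means of the
    matching single-agent measurements.
    """
    mean_a = single_a.table.groupby("dose")["response"].mean()
    mean_b = single_b.table.groupby("dose")["response"].mean()
    rows = []
    for (da, db), sub in combination.groupby(["dose_a", "dose_b"]):
        if da not in mean_a.index or db not in mean_b.index:
            raise KeyError(f"no single-agent measurement at dose pair ({da}, {db})")
        rec = bliss_index(float(mean_a.loc[da]), float(mean_b.loc[db]),
                          float(sub["response"].mean()))
        rows.append((da, db, rec.s_a, rec.s_b, rec.s_ab, rec.index, rec.call))
    return pd.DataFrame(rows, columns=["dose_a", "dose_b", "s_a", "s_b",
                                       "s_ab", "bliss_index", "call"])


def compare_ic50(
    fits_a: list[DoseResponseFit],
    fits_b: list[DoseResponseFit],
) -> dict:
    """Fold-change and log-scale t test between two arms of replicate IC50 fits.

    Fold-change is the ratio of geometric-mean IC50s (arm b over arm a); the
    test is a two-sided two-sample t on log-transformed replicate IC50s.
    With fewer than 2 replicates in either arm only the fold-change is
    reported.
    """
    ic_a = np.array([f.ic50 for f in fits_a if f.converged])
    ic_b = np.array([f.ic50 for f in fits_b if f.converged])
    if len(ic_a) == 0 or len(ic_b) == 0:
        raise ValueError("each arm needs at least one converged fit")
    log_a, log_b = np.log(ic_a), np.log(ic_b)
    fold = float(np.exp(log_b.mean() - log_a.mean()))
    out = {"fold_change": fold, "n_a": len(ic_a), "n_b": len(ic_b), "p": None}
    if len(ic_a) >= 2 and len(ic_b) >= 2:
        if np.allclose(log_a, log_a[0]) and np.allclose(log_b, log_b[0]) \
                and np.isclose(log_a[0], log_b[0]):
            out["p"] = 1.0
        else:
            out["p"] = float(stats.ttest_ind(log_a, log_b).pvalue)
    return out
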