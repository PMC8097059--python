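"""Over-representation analysis, ranked query construction and connectivity scoring.

Covers the gene-set layer of the pipeline: building ranked top-N query
lists from a differential result (ChEA-style top-100 lists; 150-per-side
up/down signature queries), one-sided Fisher/hypergeometric
over-representation against a quantified background with BH adjustment,
z-normalized enrichment heatmaps, and an unweighted Kolmogorov–Smirnov
connectivity score between an up/down query signature and a ranked
reference profile (positive = similar).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import bh_adjust
from .io import GeneSetCollection

__all__ = [
    "rank_and_select_top",
    "ora_fisher",
    "zscore_enrichment_heatmap",
    "ConnectivityResult",
    "connectivity_score",
]


def rank_and_select_top(
    result: pd.DataFrame,
    rank_by: str = "log2fc",
    n: int = 100,
    side: str = "both",
) -> dict[str, list[str]]:
    """Top-n feature lists by fold-change or test statistic.

    ``side="up"`` returns the n highest-ranked features, ``"down"`` the n
    lowest, ``"both"`` a dict with both lists.  Ties are broken by feature
    id (lexicographic) so the ordering is stable across runs.  If fewer
    than n features are available, the whole list is returned with a
    warning.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if rank_by not in result.columns:
        raise KeyError(f"rank key {rank_by!r} not in result columns")
    if side not in ("up", "down", "both"):
        raise ValueError(f"side must be up, down or both, got {side!r}")
    scored = result[rank_by].dropna()
    frame = scored.rename("key").reset_index()
    frame.columns = ["feature", "key"]
    if len(frame) < n:
        warnings.warn(f"only {len(frame)} features available for top-{n} selection")

    out: dict[str, list[str]] = {}
    if side in ("up", "both"):
        up = frame.sort_values(["key", "feature"], ascending=[False, True],
                               kind="mergesort")
        out["up"] = up["feature"].head(n).tolist()
    if side in ("down", "both"):
        down = frame.sort_values(["key", "feature"], ascending=[True, True],
                                 kind="mergesort")
        out["down"] = down["feature"].head(n).tolist()
    return out


def ora_fisher(
    foreground: Iterable[str],
    collection: GeneSetCollection,
    background: Iterable[str],
) -> pd.DataFrame:
    """One-sided over-representation test of a foreground list against gene sets.

    Sets are intersected with the background before testing; the p value is
    the upper hypergeometric tail P(X ≥ a) for overlap a, BH-adjusted across
    tested sets.  All quantified features form the background, and the
    foreground must be a subset of it.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    if not fg <= bg:
        extra = sorted(fg - bg)[:5]
        raise ValueError(f"foreground not a subset of background, e.g. {extra}")

    rows = []
    for name, members in collection.items():
        in_bg = members & bg
        if not in_bg:
            continue
        a = len(fg & in_bg)
        K, N, n_fg = len(in_bg), len(bg), len(fg)
        p = float(stats.hypergeom.sf(a - 1, N, K, n_fg))
        expected = n_fg * K / N
        factor = (a / expected) if expected > 0 else np.nan
        rows.append((name, a, n_fg, K, N, factor, p))
    res = pd.DataFrame(
        rows, columns=["set", "overlap", "foreground", "set_size",
                       "background", "factor", "p"]).set_index("set")
    if len(res):
        res["q"] = bh_adjust(res["p"])
        res = res.sort_index(kind="mergesort").sort_values("p", kind="mergesort")
    else:
        res["q"] = pd.Series(dtype=float)
    return res


def zscore_enrichment_heatmap(fdr_matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """−log10 FDR values z-scaled per row (set) across columns (queries).

    Input FDR values must lie in (0, 1]; a zero would make the log
    undefined, so callers must floor zeros at the smallest representable
    value first.  Constant rows come back as zeros, flagged in the second
    return value.
    """
    vals = fdr_matrix.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("FDR matrix must be complete")
    if (vals <= 0).any() or (vals > 1).any():
        raise ValueError("FDR values must lie in (0, 1]; floor zeros before calling")
    neglog = -np.log10(vals)
    mean = neglog.mean(axis=1, keepdims=True)
    sd = neglog.std(axis=1, ddof=1, keepdims=True)
    flat = (sd[:, 0] == 0) | np.isnan(sd[:, 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (neglog - mean) / sd
    z[flat] = 0.0
    out = pd.DataFrame(z, index=fdr_matrix.index, columns=fdr_matrix.columns)
    return out, pd.Series(flat, index=fdr_matrix.index, name="zero_sd")


@dataclass
class ConnectivityResult:
    """KS connectivity of an up/down query signature against a ranked profile."""

    es_up: float | None
    es_down: float | None
    combined: float
    n_up: int
    n_down: int


def _ks_enrichment(query: set[str], ranking: Sequence[str]) -> float:
    """Signed max deviation of the unweighted KS running sum over a ranking."""
    N = len(ranking)
    n = len(query)
    hit = np.fromiter((g in query for g in ranking), dtype=bool, count=N)
    step = np.where(hit, 1.0 / n, -1.0 / (N - n))
    walk = np.cumsum(step)
    i = int(np.argmax(np.abs(walk)))
    return float(walk[i])


def connectivity_score(
    up: Iterable[str],
    down: Iterable[str],
    reference_ranking: Sequence[str],
) -> ConnectivityResult:
    """Connectivity of a two-sided query signature with a ranked reference.

    Each list's enrichment score is the signed maximum deviation of the
    unweighted KS running sum over the reference ranking.  The combined
    score is (ES_up − ES_down)/2 when the two enrichment scores have
    opposite signs, else 0.  Positive means the up list concentrates at the
    top of the reference and the down list at the bottom (the query and the
    reference profile are similar); swapping the lists negates the score.
    """
    ref = list(reference_ranking)
    if len(set(ref)) != len(ref):
        raise ValueError("reference ranking contains duplicates")
    ref_set = set(ref)
    up_set = set(up) & ref_set
    down_set = set(down) & ref_set
    if len(up_set) < len(set(up)) or len(down_set) < len(set(down)):
        warnings.warn("query genes absent from the reference ranking were dropped")
    if not up_set and not down_set:
        raise ValueError("both query lists empty after intersecting the reference")
    if up_set & down_set:
        raise ValueError("up and down query lists overlap")

    es_up = _ks_enrichment(up_set, ref) if up_set else None
    es_down = _ks_enrichment(down_set, ref) if down_set else None
    if es_up is not None and es_down is not None and es_up * es_down < 0:
        combined = (es_up - es_down) / 2.0
    else:
        combined = 0.0
    return ConnectivityResult(es_up, es_down, combined, len(up_set), len(down_set))
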