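"""Kinase-Substrate Enrichment Analysis (KSEA) and the cross-comparison signature.

KSEA scores each kinase by how far the mean log2 fold-change of its
annotated substrate sites deviates from the mean over all quantified sites:

    z = (mean_s − mean_p) · √m / δ

where ``mean_s`` is the mean fold-change of the kinase's m matched substrate
sites, ``mean_p`` the mean over all quantified sites in the comparison, and
δ the standard deviation of all quantified sites' fold-changes.  Two-sided
normal p values are BH-adjusted across scored kinases.  Kinases matching
fewer than ``min_substrates`` (default 4) quantified sites are excluded.

The substrate network mixes curated kinase–site relationships with
predictions retained above a score threshold (default 3, inclusive).  A
cross-comparison signature keeps the kinases significant (q < 0.05) in at
least ``min_significant`` comparisons (default 3 of 5) and partitions them
with seeded k-means (k = 3) on their z rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .diffstats import bh_adjust
from .io import KinaseSubstrateDB

__all__ = [
    "expand_ks_db",
    "ksea_scores",
    "SignatureMatrix",
    "cross_comparison_signature",
    "kmeans_rows",
]


def expand_ks_db(db: KinaseSubstrateDB, networkin_min: float = 3.0) -> KinaseSubstrateDB:
    """Curated edges plus predicted edges with score ≥ ``networkin_min``."""
    edges = db.edges
    keep = (edges["source"] == "curated") | (edges["score"] >= networkin_min)
    return KinaseSubstrateDB(edges.loc[keep].reset_index(drop=True))


def ksea_scores(
    site_log2fc: pd.Series,
    db: KinaseSubstrateDB,
    min_substrates: int = 4,
) -> pd.DataFrame:
    """Per-kinase KSEA z-scores for one comparison.

    Parameters
    ----------
    site_log2fc
        Log2 fold-changes indexed by site key; NaN entries (sites not
        quantified in this comparison) are dropped.
    db
        The expanded kinase–substrate network.
    min_substrates
        Minimum matched quantified substrate sites for a kinase to be scored.

    Returns a frame indexed by kinase with columns m, mean_s, mean_p, delta,
    z, p, q — sorted by descending z.
    """
    fc = site_log2fc.dropna()
    if len(fc) < 2:
        raise ValueError("need at least 2 quantified sites to score kinases")
    mean_p = float(fc.mean())
    delta = float(fc.std(ddof=1))
    if delta == 0.0:
        raise ValueError("degenerate fold-change distribution (zero spread)")

    edges = db.edges[db.edges["site"].isin(fc.index)]
    rows = []
    for kinase, sub in edges.groupby("kinase", sort=True):
        sites = sub["site"].unique()
        m = len(sites)
        if m < min_substrates:
            continue
        mean_s = float(fc.loc[sites].mean())
        z = (mean_s - mean_p) * np.sqrt(m) / delta
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((kinase, m, mean_s, mean_p, delta, z, p))
    res = pd.DataFrame(
        rows, columns=["kinase", "m", "mean_s", "mean_p", "delta", "z", "p"]
    ).set_index("kinase")
    res["q"] = bh_adjust(res["p"]) if len(res) else pd.Series(dtype=float)
    return res.sort_values("z", ascending=False)


@dataclass
class SignatureMatrix:
    """Kinases × comparisons z matrix with significance flags and clusters."""

    z: pd.DataFrame               # retained kinases × comparisons (NaN = unscored)
    significant: pd.DataFrame     # same shape, bool (unscored counted False)
    clusters: pd.Series | None    # per-kinase cluster label (may be None)
    n_significant: pd.Series      # per retained kinase
    dropped: pd.DataFrame         # scored-but-not-retained kinases with provenance

    def to_long(self) -> pd.DataFrame:
        """Heatmap-ready long format: kinase, comparison, z, significant, cluster."""
        def _melt(frame: pd.DataFrame, value: str) -> pd.DataFrame:
            return (frame.rename_axis(index="kinase", columns="comparison")
                    .reset_index()
                    .melt(id_vars="kinase", var_name="comparison", value_name=value))

        long = _melt(self.z, "z").merge(
            _melt(self.significant, "significant"), on=["kinase", "comparison"])
        if self.clusters is not None:
            long["cluster"] = long["kinase"].map(self.clusters)
        return long


def cross_comparison_signature(
    score_tables: Mapping[str, pd.DataFrame],
    min_significant: int = 3,
    q_cut: float = 0.05,
) -> SignatureMatrix:
    """Retain kinases significant (q < q_cut) in ≥ ``min_significant`` comparisons.

    ``score_tables`` maps comparison name → KSEA score frame.  Kinases not
    scored in a comparison appear as missing z and count as non-significant
    there.  Kinases scored in fewer comparisons than ``min_significant``
    can never be retained; they are reported in ``dropped`` with provenance.
    """
    names = list(score_tables)
    if len(names) != len(set(names)):
        raise ValueError("duplicate comparison labels")
    if len(names) < 2:
        raise ValueError("need at least 2 comparisons for a signature")

    all_kinases = sorted(set().union(*(set(t.index) for t in score_tables.values())))
    z = pd.DataFrame(np.nan, index=all_kinases, columns=names)
    sig = pd.DataFrame(False, index=all_kinases, columns=names)
    for name, tab in score_tables.items():
        z.loc[tab.index, name] = tab["z"]
        sig.loc[tab.index, name] = (tab["q"] < q_cut).to_numpy()

    n_sig = sig.sum(axis=1)
    n_scored = z.notna().sum(axis=1)
    retained = n_sig >= min_significant
    dropped = pd.DataFrame({
        "n_scored": n_scored[~retained],
        "n_significant": n_sig[~retained],
    })
    dropped["provenance"] = np.where(
        dropped["n_scored"] < min_significant,
        "scored in fewer comparisons than required",
        "below significance threshold")
    return SignatureMatrix(
        z=z.loc[retained],
        significant=sig.loc[retained],
        clusters=None,
        n_significant=n_sig[retained],
        dropped=dropped,
    )


def kmeans_rows(
    signature: SignatureMatrix,
    k: int = 3,
    seed: int = 0,
    n_init: int = 10,
) -> SignatureMatrix:
    """Cluster retained kinases on their z rows with seeded multi-start k-means.

    Missing z cells are imputed as 0 for clustering only (they stay missing
    in the matrix).  Labels are canonicalized by descending cluster mean z,
    so cluster 0 holds the most activated kinases.
    """
    z = signature.z
    if len(z) < k:
        raise ValueError(f"need at least k={k} retained kinases, have {len(z)}")
    X = z.fillna(0.0).to_numpy()
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(X)
    # canonical order: clusters sorted by descending mean z
    means = [X[raw_labels == c].mean() for c in range(k)]
    order = np.argsort(means)[::-1]
    relabel = {int(old): new for new, old in enumerate(order)}
    labels = pd.Series([relabel[int(c)] for c in raw_labels], index=z.index,
                       name="cluster")
    return SignatureMatrix(
        z=signature.z,
        significant=signature.significant,
        clusters=labels,
        n_significant=signature.n_significant,
        dropped=signature.dropped,
    )
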