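"""Differential significance procedures for log2 quantification matrices.

Three tests are provided, mirroring common practice in quantitative
(phospho)proteomics:

* a two-class moderated t (SAM-style) statistic with an additive fudge
  factor ``s0`` in the denominator and permutation-estimated FDR,
* plain one-way ANOVA with Benjamini–Hochberg adjustment, and
* a one-sample moderated t on log2 ratio matrices.

On top of these sit the volcano prioritization: asymmetric fold-change
thresholds at 3× the standard deviation of the up- and down-regulated
fold-change distributions, a proteome-level correction that flags
phosphosites whose parent protein changes by the same criteria, and a
functional-score filter (score strictly above 0.5).

``s0`` is a fixed additive constant on the standard error (the Perseus
convention), not the percentile-optimized fudge factor of original SAM.
Standard deviations use the n−1 denominator throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import QuantMatrix, SampleDesign

__all__ = [
    "SamParams",
    "moderated_t_two_class",
    "permutation_fdr",
    "sam_test",
    "anova_oneway",
    "one_sample_t",
    "bh_adjust",
    "VolcanoSelection",
    "volcano_select",
    "proteome_correction_flags",
    "prioritize_functional",
]


@dataclass
class SamParams:
    """Parameters of the SAM-style permutation test.

    s0 : additive fudge factor on the standard error (log2 units).
    n_permutations : permutation budget B; when the design admits no more
        than B distinct label splits they are enumerated exhaustively.
    fdr_target : q* for the significant set.
    seed : seed for permutation sampling (unused when exhaustive).
    """

    s0: float = 0.1
    n_permutations: int = 250
    fdr_target: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if self.n_permutations < 25:
            raise ValueError("need a permutation budget of at least 25")
        if not (0.0 < self.fdr_target < 1.0):
            raise ValueError("fdr_target must lie in (0, 1)")


def _group_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row count, mean and variance (ddof=1) ignoring NaN."""
    n = np.sum(~np.isnan(values), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(values, axis=1)
        var = np.nanvar(values, axis=1, ddof=1)
    mean = np.where(n >= 1, mean, np.nan)
    var = np.where(n >= 2, var, np.nan)
    return n, mean, var


def _two_class_d(case: np.ndarray, control: np.ndarray, s0: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (log2FC, d) for a case/control split of one matrix."""
    n1, m1, v1 = _group_stats(case)
    n2, m2, v2 = _group_stats(control)
    fc = m1 - m2
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        d = fc / (se + s0)
    ok = (n1 >= 2) & (n2 >= 2)
    return np.where(ok, fc, np.nan), np.where(ok, d, np.nan)


def moderated_t_two_class(
    matrix: QuantMatrix,
    design: SampleDesign,
    case: str,
    control: str,
    s0: float = 0.1,
) -> pd.DataFrame:
    """Per-feature log2 fold-change and moderated statistic d.

    d = (mean_case − mean_control) / (se + s0) with the pooled-variance
    two-sample standard error.  Features with fewer than 2 observed values
    in either group are returned unscored (NaN).
    """
    case_vals = matrix.data[design.samples(case)].to_numpy()
    ctrl_vals = matrix.data[design.samples(control)].to_numpy()
    fc, d = _two_class_d(case_vals, ctrl_vals, s0)
    return pd.DataFrame({"log2fc": fc, "statistic": d}, index=matrix.data.index)


def _distinct_splits(n_total: int, n_case: int):
    """All distinct assignments of ``n_case`` of ``n_total`` samples to 'case'."""
    return combinations(range(n_total), n_case)


def permutation_fdr(
    d_observed: pd.Series,
    matrix: QuantMatrix,
    design: SampleDesign,
    case: str,
    control: str,
    params: SamParams,
) -> tuple[pd.Series, pd.Series]:
    """Permutation-based q-values for a two-class moderated t.

    For a cutoff c the estimated FDR is the mean over label permutations of
    #{|d_perm| ≥ c} divided by #{|d_obs| ≥ c} (π0 taken as 1).  The
    observed labeling — and, for equal group sizes, its group-swap mirror,
    which reproduces the observed |d| exactly — is excluded from the
    permutation set, since both carry the alternative rather than the null.
    A feature's q is the minimum FDR over all cutoffs that admit it, capped
    at 1.  When the design allows at most B distinct relabelings they are
    enumerated exhaustively (deterministic); otherwise B random splits are
    drawn with the configured seed.
    """
    case_cols = design.samples(case)
    ctrl_cols = design.samples(control)
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("each group needs at least 2 samples for permutation FDR")
    pooled = matrix.data[case_cols + ctrl_cols].to_numpy()
    n_case, n_total = len(case_cols), len(case_cols) + len(ctrl_cols)

    from math import comb

    identity = tuple(range(n_case))
    mirror = (tuple(range(n_case, n_total))
              if n_total - n_case == n_case else None)
    excluded = {identity, mirror} - {None}
    n_distinct = comb(n_total, n_case) - len(excluded)
    if n_distinct < 1:
        raise ValueError("design admits no non-trivial label permutations")
    if n_distinct <= params.n_permutations:
        splits = [s for s in _distinct_splits(n_total, n_case)
                  if s not in excluded]
    else:
        rng = np.random.default_rng(params.seed)
        splits = []
        while len(splits) < params.n_permutations:
            s = tuple(sorted(rng.choice(n_total, size=n_case, replace=False)))
            if s not in excluded:
                splits.append(s)

    abs_obs = d_observed.abs().to_numpy()
    scored = ~np.isnan(abs_obs)
    obs_sorted = np.sort(abs_obs[scored])

    # per permutation, the sorted |d| values of scored features
    perm_sorted = []
    for split in splits:
        mask = np.zeros(n_total, dtype=bool)
        mask[list(split)] = True
        _, d_perm = _two_class_d(pooled[:, mask], pooled[:, ~mask], params.s0)
        perm_sorted.append(np.sort(np.abs(d_perm[scored & ~np.isnan(d_perm)])))

    cutoffs = np.unique(obs_sorted)  # ascending
    n_ge_obs = len(obs_sorted) - np.searchsorted(obs_sorted, cutoffs, side="left")
    exceed = np.stack([
        len(ps) - np.searchsorted(ps, cutoffs, side="left") for ps in perm_sorted
    ])  # permutations × cutoffs
    mean_false = np.mean(exceed, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_at_cutoff = np.minimum(mean_false / n_ge_obs, 1.0)
    # q at cutoff c = min FDR over cutoffs <= c  (running min, ascending)
    q_at_cutoff = np.minimum.accumulate(fdr_at_cutoff)

    q = np.full(len(abs_obs), np.nan)
    idx = np.searchsorted(cutoffs, abs_obs[scored], side="right") - 1
    q[scored] = q_at_cutoff[np.clip(idx, 0, len(cutoffs) - 1)]
    q_series = pd.Series(q, index=d_observed.index, name="q")
    significant = pd.Series(False, index=d_observed.index, name="significant")
    significant[scored] = q[scored] < params.fdr_target
    return q_series, significant


def sam_test(
    matrix: QuantMatrix,
    design: SampleDesign,
    case: str,
    control: str,
    params: SamParams | None = None,
) -> pd.DataFrame:
    """Two-class SAM-style test: moderated t plus permutation FDR.

    Returns a per-feature frame with columns log2fc, statistic, p (NaN; the
    procedure is permutation-based), q, significant and direction.
    """
    params = params or SamParams()
    res = moderated_t_two_class(matrix, design, case, control, params.s0)
    q, sig = permutation_fdr(res["statistic"], matrix, design, case, control, params)
    res["p"] = np.nan
    res["q"] = q
    res["significant"] = sig
    res["direction"] = _directions(res)
    return res


def _directions(res: pd.DataFrame) -> pd.Series:
    direction = pd.Series("none", index=res.index)
    up = res["significant"] & (res["log2fc"] > 0)
    down = res["significant"] & (res["log2fc"] < 0)
    direction[up] = "up"
    direction[down] = "down"
    return direction


def anova_oneway(
    matrix: QuantMatrix,
    design: SampleDesign,
    conditions: list[str] | None = None,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Per-feature one-way ANOVA across condition groups, BH-adjusted.

    Groups with fewer than 2 observed values for a feature exclude that
    feature; all-constant features yield a missing p and are excluded from
    the BH family.
    """
    conditions = conditions if conditions is not None else design.conditions
    if len(conditions) < 2:
        raise ValueError("ANOVA requires at least 2 conditions")
    groups = [matrix.data[design.samples(c)].to_numpy() for c in conditions]
    stats_per_group = [_group_stats(g) for g in groups]
    ns = np.stack([s[0] for s in stats_per_group])
    means = np.stack([s[1] for s in stats_per_group])
    vars_ = np.stack([s[2] for s in stats_per_group])

    testable = (ns >= 2).all(axis=0)
    n_tot = ns.sum(axis=0)
    grand = np.nansum(ns * means, axis=0) / n_tot
    ss_between = np.nansum(ns * (means - grand) ** 2, axis=0)
    ss_within = np.nansum((ns - 1) * vars_, axis=0)
    df_between = len(conditions) - 1
    df_within = n_tot - len(conditions)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_between) / (ss_within / df_within)
    p = stats.f.sf(F, df_between, df_within)
    # constant features (no variance at all) are untestable
    constant = testable & (ss_within == 0) & (ss_between == 0)
    p = np.where(testable & ~constant, p, np.nan)
    F = np.where(testable & ~constant, F, np.nan)

    res = pd.DataFrame({"statistic": F, "p": p}, index=matrix.data.index)
    res["log2fc"] = means[-1] - means[0]  # last vs first condition, descriptive
    res["q"] = bh_adjust(res["p"])
    res["significant"] = res["q"] < fdr
    res["direction"] = _directions(res)
    return res[["log2fc", "statistic", "p", "q", "significant", "direction"]]


def one_sample_t(
    ratio_matrix: QuantMatrix,
    s0: float = 0.1,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """One-sample moderated t on a log2-ratio matrix against zero.

    d = mean / (SD/√n + s0); two-sided p from the t distribution with n−1
    degrees of freedom evaluated at d, BH-adjusted.  Features with fewer
    than 2 observed ratios are unscored.
    """
    vals = ratio_matrix.data.to_numpy()
    n, mean, var = _group_stats(vals)
    ok = n >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(var / n)
        d = mean / (se + s0)
        p = 2.0 * stats.t.sf(np.abs(d), n - 1)
    d = np.where(ok, d, np.nan)
    p = np.where(ok, p, np.nan)
    res = pd.DataFrame(
        {"log2fc": np.where(ok, mean, np.nan), "statistic": d, "p": p},
        index=ratio_matrix.data.index)
    res["q"] = bh_adjust(res["p"])
    res["significant"] = res["q"] < fdr
    res["direction"] = _directions(res)
    return res


def bh_adjust(pvalues: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini–Hochberg step-up adjustment; missing p excluded from m."""
    arr = np.asarray(pvalues, dtype=float)
    mask = ~np.isnan(arr)
    if ((arr[mask] < 0) | (arr[mask] > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    q = np.full_like(arr, np.nan)
    if mask.any():
        q[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(q, index=pvalues.index, name="q")
    return q


# ---------------------------------------------------------------------------
# volcano prioritization


@dataclass
class VolcanoSelection:
    """Volcano-style selection with asymmetric 3×SD fold-change thresholds."""

    table: pd.DataFrame          # per feature: log2fc, q, selected, direction,
                                 # proteome_regulated, provenance, functional_score,
                                 # prioritized
    fdr: float
    up_threshold: float | None   # 3 × SD of positive log2FCs
    down_threshold: float | None # 3 × SD (absolute) of negative log2FCs
    functional_min: float = 0.5

    @property
    def selected(self) -> list[str]:
        return self.table.index[self.table["selected"]].tolist()

    @property
    def prioritized(self) -> list[str]:
        if "prioritized" not in self.table.columns:
            return []
        return self.table.index[self.table["prioritized"].fillna(False)].tolist()


def volcano_select(result: pd.DataFrame, fdr: float = 0.01) -> VolcanoSelection:
    """Select features passing FDR and the side-specific 3×SD fold-change rule.

    The up threshold is 3 × the (n−1) standard deviation of all positive
    log2 fold-changes; the down threshold likewise over the negative ones.
    A feature is selected iff q < fdr AND its |log2FC| strictly exceeds the
    threshold of its own side.  A side with fewer than 2 fold-changes has an
    undefined threshold and yields no calls on that side.
    """
    fc = result["log2fc"]
    pos = fc[fc > 0]
    neg = fc[fc < 0]

    def _thr(side_fc: pd.Series, label: str) -> float | None:
        if len(side_fc) < 2:
            warnings.warn(f"fewer than 2 {label} fold-changes; no calls on that side")
            return None
        return 3.0 * float(side_fc.std(ddof=1))

    up_thr = _thr(pos, "positive")
    down_thr = _thr(neg.abs(), "negative")

    passing_q = result["q"] < fdr
    sel_up = passing_q & (fc > 0) & (fc > up_thr if up_thr is not None else False)
    sel_down = passing_q & (fc < 0) & (fc < -down_thr if down_thr is not None else False)
    table = result[["log2fc", "q"]].copy()
    table["selected"] = sel_up | sel_down
    table["direction"] = "none"
    table.loc[sel_up, "direction"] = "up"
    table.loc[sel_down, "direction"] = "down"
    return VolcanoSelection(table, fdr, up_thr, down_thr)


def proteome_correction_flags(
    selection: VolcanoSelection,
    site_to_protein: pd.Series | dict,
    proteome_selection: VolcanoSelection,
) -> VolcanoSelection:
    """Flag selected sites whose parent protein is selected in the same direction.

    The proteome selection must have been produced with the same FDR and
    3×SD rule applied to the proteome's own fold-change distribution.
    Sites whose protein was not testable get flag False with provenance
    ``"protein not testable"``.
    """
    mapping = pd.Series(site_to_protein)
    table = selection.table.copy()
    table["proteome_regulated"] = False
    table["provenance"] = ""
    prot = proteome_selection.table
    for site in table.index[table["selected"]]:
        protein = mapping.get(site)
        if protein is None or protein not in prot.index:
            table.loc[site, "provenance"] = "protein not testable"
            continue
        row = prot.loc[protein]
        if bool(row["selected"]) and row["direction"] == table.loc[site, "direction"]:
            table.loc[site, "proteome_regulated"] = True
    return VolcanoSelection(table, selection.fdr, selection.up_threshold,
                            selection.down_threshold, selection.functional_min)


def prioritize_functional(
    selection: VolcanoSelection,
    functional_scores,
    min_score: float = 0.5,
) -> VolcanoSelection:
    """Keep selected sites with functional score strictly above ``min_score``.

    Sites without a score are excluded with provenance ``"unscored"``.
    """
    table = selection.table.copy()
    table["functional_score"] = np.nan
    table["prioritized"] = False
    if "provenance" not in table.columns:
        table["provenance"] = ""
    for site in table.index:
        score = functional_scores.get(site)
        if score is not None:
            table.loc[site, "functional_score"] = score
    sel = table["selected"]
    unscored = sel & table["functional_score"].isna()
    table.loc[unscored, "provenance"] = "unscored"
    table["prioritized"] = sel & (table["functional_score"] > min_score)
    return VolcanoSelection(table, selection.fdr, selection.up_threshold,
                            selection.down_threshold, min_score)
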