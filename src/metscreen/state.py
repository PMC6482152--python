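"""Epithelial-state scoring from expression or accessibility matrices.

Gene-level values (CAGE tpm, or peak counts aggregated per closest gene)
are Z-scored per gene across the analysed samples; curated gene sets
(epithelial E, mesenchymal M, keratinocyte K, fibroblast F) are then
summarised as the distribution of their member genes' Z values per
condition, with a two-tailed Student's t-test of each condition against
the control condition.  Significance stars follow the convention
* p<0.01, ** p<0.001, *** p<0.0001, **** p<0.00001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

STAR_LEVELS = (0.01, 0.001, 0.0001, 0.00001)


@dataclass
class StateScoreResult:
    zmatrix: pd.DataFrame
    per_set: pd.DataFrame  # set, condition, n_genes, median, q1, q3, mean
    pvals: pd.DataFrame  # set, condition, t, p, stars


def significance_stars(p: float) -> str:
    return "*" * sum(p < level for level in STAR_LEVELS)


def zscore_by_gene(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Per-gene Z-score across columns, with sample (n-1) sd.

    Returns (zmatrix, flagged) where ``flagged`` indexes genes with zero
    variance, whose rows are set to all-zero rather than NaN.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples/conditions to Z-score")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0.0
    sd[flat] = 1.0
    z = (values - mean) / sd
    z[flat] = 0.0
    zm = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return zm, matrix.index[flat]


def t_test(a, b, *, equal_var: bool = True) -> tuple[float, float]:
    """Two-sample two-tailed Student's t-test (classical pooled-variance form).

    Welch's correction is available via ``equal_var=False`` but the
    equal-variance form is the default used throughout the pipeline.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0.0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means: p undefined")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def score_gene_sets(
    zmatrix: pd.DataFrame,
    sets: dict[str, list[str]],
    control: str,
    *,
    groups: dict[str, str] | None = None,
    min_set_size: int = 3,
) -> StateScoreResult:
    """Gene-set Z-score distributions per condition, tested against control.

    ``groups`` maps sample column -> condition label (default: each
    column is its own condition); ``control`` names the control
    condition.  For each set and condition the member genes' Z values
    over the condition's columns are pooled; the test is a two-tailed
    Student's t-test of that pool against the control pool.  Sets with
    fewer than ``min_set_size`` members in the matrix are summarised but
    not tested.
    """
    if groups is None:
        groups = {c: c for c in zmatrix.columns}
    conditions = sorted(set(groups.values()))
    if control not in conditions:
        raise ValueError(f"control condition {control!r} not among {conditions}")
    cols_of = {
        cond: [c for c in zmatrix.columns if groups.get(c) == cond]
        for cond in conditions
    }

    universe = set(zmatrix.index)
    seen: set[str] = set()
    for name, members in sets.items():
        overlap = seen & set(members)
        if overlap:
            warnings.warn(f"gene set {name!r} overlaps earlier sets: {len(overlap)} genes")
        seen |= set(members)

    summary_rows, pval_rows = [], []
    for name, members in sets.items():
        present = sorted(universe & set(members))
        if not present:
            warnings.warn(f"gene set {name!r} has empty intersection with matrix; skipped")
            continue
        sub = zmatrix.loc[present]
        ctrl_pool = sub[cols_of[control]].to_numpy().ravel()
        for cond in conditions:
            pool = sub[cols_of[cond]].to_numpy().ravel()
            q1, med, q3 = np.percentile(pool, [25, 50, 75])
            summary_rows.append((name, cond, len(present), med, q1, q3, pool.mean()))
            if cond == control:
                continue
            if len(present) < min_set_size:
                warnings.warn(
                    f"gene set {name!r}: only {len(present)} genes in matrix; test skipped"
                )
                continue
            t, p = t_test(pool, ctrl_pool)
            pval_rows.append((name, cond, t, p, significance_stars(p)))
    per_set = pd.DataFrame(
        summary_rows, columns=["set", "condition", "n_genes", "median", "q1", "q3", "mean"]
    )
    pvals = pd.DataFrame(pval_rows, columns=["set", "condition", "t", "p", "stars"])
    return StateScoreResult(zmatrix=zmatrix, per_set=per_set, pvals=pvals)


def spearman_distance_matrix(matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """1 - Spearman rank correlation between rows (average ranks for ties).

    Rows with constant profiles have undefined correlations; they are
    flagged and assigned the metric maximum distance 2 to every other
    item (0 to themselves).
    """
    values = matrix.to_numpy(dtype=float)
    n = values.shape[0]
    constant = [
        str(matrix.index[i]) for i in range(n) if np.all(values[i] == values[i, 0])
    ]
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    sd = ranks.std(axis=1, ddof=0)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * ranks.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (centered @ centered.T) / denom
    dist = 1.0 - corr
    bad = sd == 0
    dist[bad, :] = 2.0
    dist[:, bad] = 2.0
    np.fill_diagonal(dist, 0.0)
    return dist, constant


def hcluster(matrix: pd.DataFrame, axis: int = 0):
    """Average-linkage (UPGMA) clustering on a Spearman correlation distance.

    ``axis=0`` clusters rows, ``axis=1`` columns.  Returns
    (linkage matrix, leaf labels in dendrogram order, flagged constant items).
    """
    if axis == 1:
        matrix = matrix.T
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 items to cluster")
    dist, constant = spearman_distance_matrix(matrix)
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    order = hierarchy.leaves_list(linkage)
    labels = [str(matrix.index[i]) for i in order]
    return linkage, labels, constant
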