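"""Motif-accessibility deviation scores and expression reciprocity.

For each TF-binding motif, the reads falling in the motif's peaks are
compared with the reads expected if every sample distributed its reads
over peaks identically (the all-sample pooled fractions):

    E[m, s] = (total reads in sample s) x (pooled fraction of reads in m's peaks)
    d[m, s] = (observed - E) / E

The raw deviation is then standardised against background peak sets
matched on GC content and mean accessibility: each foreground peak is
paired, per background iteration, with a random peak from the same
(GC x accessibility) quantile bin, and

    z[m, s] = (d[m, s] - mean_bg d) / sd_bg d .

This background-corrected Z is the "motif enrichment score".  Motifs are
called differentially accessible between two sample groups when a
two-tailed Student's t-test on their z values survives BH FDR control
(q < 0.01) AND the group-mean z difference exceeds 5 in the favoured
direction — a dual filter combining statistical and effect-size evidence.

Reciprocity: a TF whose expression change (log2 fold change, q-value from
a CAGE-style contrast) and motif-accessibility change point the same way
acts as a positive chromatin regulator (TP63/KLF4 pattern); opposite
directions mark a negative regulator (OVOL2 pattern, whose motifs close
where the factor is expressed).  Both changes must be measured against
the same group ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .state import t_test

LABEL_A = "more-accessible-in-A"
LABEL_B = "more-accessible-in-B"
LABEL_NS = "ns"


@dataclass
class MotifMatch:
    """Peak x motif membership plus the per-peak matching covariates."""

    membership: pd.DataFrame  # peaks x motifs, boolean
    gc: pd.Series  # per peak, in (0, 1)
    mean_accessibility: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.membership.index.equals(self.gc.index):
            raise ValueError("membership and gc must share the peak index")


@dataclass
class DeviationResult:
    z: pd.DataFrame  # motif x sample
    flagged_motifs: list[str] = field(default_factory=list)
    diff: pd.DataFrame | None = None


def _quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, values, side="right")


def motif_deviation(
    counts: pd.DataFrame,
    motifs: MotifMatch,
    n_background: int = 50,
    seed: int | np.random.Generator = 0,
    *,
    n_bins: int = 10,
    min_peaks: int = 10,
) -> DeviationResult:
    """Background-corrected motif accessibility Z-scores (motif x sample).

    ``counts`` is the peak x sample read-count matrix over the reference
    peaks; rows must align with ``motifs.membership``.  Motifs matching
    fewer than ``min_peaks`` peaks are flagged (scores still reported).
    Cells where the background deviations have zero spread come back NaN.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if not counts.index.equals(motifs.membership.index):
        raise ValueError("counts and motif membership must share the peak index")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    X = counts.to_numpy(dtype=float)
    M = motifs.membership.to_numpy(dtype=bool)
    n_peaks, n_samples = X.shape
    totals = X.sum(axis=0)  # per sample
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("count matrix has no reads")

    Mf = M.T.astype(float)

    def deviations(peak_index_matrix: np.ndarray | None) -> np.ndarray:
        # observed reads per motif set; None = the true (foreground) peaks
        Xp = X if peak_index_matrix is None else X[peak_index_matrix]
        obs = Mf @ Xp  # motifs x samples
        frac = obs.sum(axis=1, keepdims=True) / grand
        expected = frac * totals[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            return (obs - expected) / expected

    d = deviations(None)

    acc = (
        motifs.mean_accessibility.to_numpy(dtype=float)
        if motifs.mean_accessibility is not None
        else X.mean(axis=1)
    )
    gc = motifs.gc.to_numpy(dtype=float)
    bins = _quantile_bins(gc, n_bins) * n_bins + _quantile_bins(acc, n_bins)
    # Matched resampling is keyed to peak ids sorted lexicographically, so a
    # consistent permutation of peak order yields identical draws (and z).
    label_order = np.argsort(np.asarray(counts.index.astype(str)), kind="mergesort")
    uniforms = rng.random((n_peaks, n_background))  # row i = i-th peak by label
    bg = np.empty((n_peaks, n_background), dtype=np.int64)
    bins_sorted = bins[label_order]
    for b in np.unique(bins):
        members = label_order[np.flatnonzero(bins_sorted == b)]  # label-sorted
        rows = np.flatnonzero(bins_sorted == b)  # positions in label order
        picks = (uniforms[rows] * len(members)).astype(np.int64)
        bg[members] = members[picks]

    bg_dev = np.stack([deviations(bg[:, j]) for j in range(n_background)])
    mu = bg_dev.mean(axis=0)
    sd = bg_dev.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (d - mu) / sd
    # deviations are dimensionless fractions; spread below ~1e-10 is roundoff
    degenerate = sd < 1e-10
    z[degenerate & (np.abs(d - mu) < 1e-10)] = 0.0  # flat null: no deviation
    z[degenerate & (np.abs(d - mu) >= 1e-10)] = np.nan

    motif_ids = list(motifs.membership.columns)
    n_match = M.sum(axis=0)
    flagged = [m for m, k in zip(motif_ids, n_match) if k < min_peaks]
    zdf = pd.DataFrame(z, index=motif_ids, columns=counts.columns)
    return DeviationResult(z=zdf, flagged_motifs=flagged)


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, capped at 1)."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        if p[ok].min() < 0 or p[ok].max() > 1:
            raise ValueError("p-values must lie in [0, 1]")
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def differential_motifs(
    z: pd.DataFrame,
    groups: dict[str, str],
    z_threshold: float = 5.0,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Two-group differential motif accessibility with the dual filter.

    ``groups`` maps sample -> one of exactly two group labels; the first
    label in sorted order plays "A".  Returns a per-motif table with
    mean z per group, t, p, BH q and the label.  With fewer than two
    samples in a group the test is skipped (descriptive means only).
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    ga, gb = labels
    cols_a = [c for c in z.columns if groups.get(c) == ga]
    cols_b = [c for c in z.columns if groups.get(c) == gb]
    testable = len(cols_a) >= 2 and len(cols_b) >= 2
    A = z[cols_a].to_numpy(dtype=float)
    B = z[cols_b].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        mean_a, mean_b = np.nanmean(A, axis=1), np.nanmean(B, axis=1)
    tvals = np.full(len(z), np.nan)
    pvals = np.full(len(z), np.nan)
    if testable:
        complete = ~(np.isnan(A).any(axis=1) | np.isnan(B).any(axis=1))
        if complete.any():
            res = stats.ttest_ind(A[complete], B[complete], axis=1, equal_var=True)
            tvals[complete] = res.statistic
            pvals[complete] = res.pvalue
            # zero pooled variance with equal means: no evidence of difference
            flat = complete & (
                np.concatenate([A, B], axis=1).std(axis=1, ddof=0) == 0
            )
            tvals[flat], pvals[flat] = 0.0, 1.0
    out = pd.DataFrame(
        {"motif": z.index, "mean_z_A": mean_a, "mean_z_B": mean_b, "t": tvals, "p": pvals}
    )
    out["q"] = bh_qvalues(out["p"].to_numpy())
    delta = out["mean_z_A"] - out["mean_z_B"]
    sig = out["q"] < q_threshold
    out["label"] = LABEL_NS
    out.loc[sig & (delta > z_threshold), "label"] = LABEL_A
    out.loc[sig & (-delta > z_threshold), "label"] = LABEL_B
    return out.set_index("motif")


def expression_lfc(
    expr: pd.DataFrame,
    groups: dict[str, str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2 fold change (B vs A) with t-test p and BH q.

    lfc = log2((mean_B + pc) / (mean_A + pc)); the test is a two-tailed
    Student's t on log2(x + pc) values, skipped (NaN) for all-zero genes.
    Group ordering matches differential_motifs: sorted labels, first = A.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    ga, gb = labels
    cols_a = [c for c in expr.columns if groups.get(c) == ga]
    cols_b = [c for c in expr.columns if groups.get(c) == gb]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 samples per group")
    A = expr[cols_a].to_numpy(dtype=float)
    B = expr[cols_b].to_numpy(dtype=float)
    lfc = np.log2((B.mean(axis=1) + pseudocount) / (A.mean(axis=1) + pseudocount))
    logA = np.log2(A + pseudocount)
    logB = np.log2(B + pseudocount)
    pvals = np.full(len(expr), np.nan)
    for i in range(len(expr)):
        if np.all(A[i] == 0) and np.all(B[i] == 0):
            lfc[i] = 0.0
            continue
        if np.var(logA[i], ddof=1) + np.var(logB[i], ddof=1) == 0:
            pvals[i] = 1.0 if lfc[i] == 0 else np.nan
            continue
        _, pvals[i] = t_test(logB[i], logA[i])
    out = pd.DataFrame({"lfc": lfc, "p": pvals}, index=expr.index)
    out["q"] = bh_qvalues(out["p"].to_numpy())
    return out


def reciprocity_classify(
    motif_delta: pd.Series,
    expr_stats: pd.DataFrame,
    motif_to_gene: pd.DataFrame,
    *,
    q_threshold: float = 0.01,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Classify TFs as positive/negative chromatin regulators.

    ``motif_delta`` is the per-motif accessibility change (B - A, any
    consistent score scale); ``expr_stats`` holds per-gene ``lfc`` and
    ``q`` on the same B-vs-A ordering; ``motif_to_gene`` maps motif ->
    gene (columns ``motif``, ``gene``; many-to-one allowed).  TFs whose
    expression passes q < 0.01 and |lfc| > 1 are called
    "positive-regulator" when expression and motif accessibility move
    together and "negative-regulator" when they oppose; all others are
    "unclassified".  Motifs without a mapped gene are reported with gene
    NaN and call "unmapped".
    """
    rows = []
    mapped = motif_to_gene.set_index("motif")["gene"] if len(motif_to_gene) else pd.Series(dtype=object)
    for motif, delta in motif_delta.items():
        genes = mapped.loc[[motif]].tolist() if motif in mapped.index else [None]
        for gene in genes:
            if gene is None or gene not in expr_stats.index:
                rows.append((motif, gene, delta, np.nan, np.nan, "unmapped"))
                continue
            lfc = float(expr_stats.loc[gene, "lfc"])
            q = float(expr_stats.loc[gene, "q"])
            if not (q < q_threshold and abs(lfc) > lfc_threshold):
                call = "unclassified"
            elif np.sign(delta) == np.sign(lfc) and delta != 0:
                call = "positive-regulator"
            else:
                call = "negative-regulator"
            rows.append((motif, gene, delta, lfc, q, call))
    return pd.DataFrame(
        rows, columns=["motif", "tf", "motif_delta", "expr_lfc", "expr_q", "call"]
    )
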