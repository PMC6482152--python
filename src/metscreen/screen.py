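"""Dual-marker correlation screen for MET-inducing transcription factors.

A compendium of expression profiles (cancer cell lines, primary cells)
spans a continuum of epithelial (E) and mesenchymal (M) states.  A TF that
promotes the epithelial state should correlate positively with an E marker
(CDH1-like) and negatively with an M marker (VIM-like) across that
compendium.  This module selects the most anti-correlated E/M marker pair,
computes Pearson r of every TF against both markers, and grades each TF
into tiers:

    "+++"  r_e > 0.4  and r_m < -0.4
    "++"   r_e > 0.2  and r_m < -0.2
    "+"    r_e > 0    and r_m < 0
    "-"    otherwise

All inequalities are strict.  TFs whose expression is constant (undefined
correlation) are reported with tier "NA" rather than dropped, so the
attrition from the input list is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TIERS = ("-", "+", "++", "+++")

#: minimum pairwise-complete observations required for a correlation
MIN_COMPLETE_PAIRS = 10


class UndefinedCorrelationError(ValueError):
    """One of the series has zero variance (or too few complete pairs)."""


@dataclass(frozen=True)
class MarkerPair:
    """The selected E/M marker pair and its Pearson correlation."""

    e_marker: str
    m_marker: str
    r_pair: float

    def __post_init__(self) -> None:
        if self.e_marker == self.m_marker:
            raise ValueError("e_marker and m_marker must differ")
        if not -1.0 <= self.r_pair <= 1.0:
            raise ValueError(f"r_pair {self.r_pair} outside [-1, 1]")


def pearson(x, y, *, min_pairs: int = MIN_COMPLETE_PAIRS) -> float:
    """Pearson product-moment correlation with pairwise-complete observations.

    NaNs are dropped pairwise; at least ``min_pairs`` complete pairs (and
    never fewer than 3) are required.  Zero variance in either series
    raises :class:`UndefinedCorrelationError` instead of returning a silent
    0 or NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < max(3, min_pairs):
        raise UndefinedCorrelationError(
            f"only {n} complete pairs; need >= {max(3, min_pairs)}"
        )
    xm = x[mask] - x[mask].mean()
    ym = y[mask] - y[mask].mean()
    denom = np.sqrt((xm @ xm) * (ym @ ym))
    if denom == 0.0:
        raise UndefinedCorrelationError("zero variance in at least one series")
    return float(np.clip((xm @ ym) / denom, -1.0, 1.0))


def select_marker_pair(
    expr: pd.DataFrame,
    e_candidates: list[str],
    m_candidates: list[str],
    *,
    min_pairs: int = MIN_COMPLETE_PAIRS,
) -> MarkerPair:
    """Pick the (E, M) candidate pair with the strongest anti-correlation.

    Returns the pair minimising ``pearson(e, m)`` over the full candidate
    cross-product; ties break lexicographically on (e_marker, m_marker).
    """
    if not e_candidates or not m_candidates:
        raise ValueError("candidate lists must be non-empty")
    for g in [*e_candidates, *m_candidates]:
        if g not in expr.index:
            raise KeyError(f"candidate gene {g!r} not in expression matrix")
    best: tuple[float, str, str] | None = None
    for e in sorted(e_candidates):
        for m in sorted(m_candidates):
            if e == m:
                continue
            r = pearson(expr.loc[e], expr.loc[m], min_pairs=min_pairs)
            key = (r, e, m)
            if best is None or key < best:
                best = key
    if best is None:
        raise ValueError("no valid (e, m) pair among candidates")
    r, e, m = best
    return MarkerPair(e_marker=e, m_marker=m, r_pair=r)


def classify_tier(r_e: float, r_m: float) -> str:
    """Grade a TF's epithelial association from its marker correlations.

    Highest tier whose (strict) condition holds; see module docstring.
    """
    for v, name in ((r_e, "r_e"), (r_m, "r_m")):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [-1, 1]")
    if r_e > 0.4 and r_m < -0.4:
        return "+++"
    if r_e > 0.2 and r_m < -0.2:
        return "++"
    if r_e > 0 and r_m < 0:
        return "+"
    return "-"


def screen_tfs(
    expr: pd.DataFrame,
    tf_list: list[str],
    pair: MarkerPair,
    *,
    min_pairs: int = MIN_COMPLETE_PAIRS,
) -> pd.DataFrame:
    """Correlate every TF with both markers and classify into tiers.

    Returns a DataFrame indexed by TF with columns ``r_e``, ``r_m``,
    ``tier``, ``found`` — one row per requested TF, in a deterministic
    order: classified tiers first (best tier first, then r_e - r_m
    descending, then TF id), then "NA" (constant expression), then
    missing TFs.  The (r_e, r_m) columns double as scatter coordinates
    for the screen plot.
    """
    if expr.shape[1] < 3:
        raise UndefinedCorrelationError(
            f"screen needs >= 3 samples, got {expr.shape[1]}"
        )
    e = expr.loc[pair.e_marker]
    m = expr.loc[pair.m_marker]
    rows = []
    for tf in dict.fromkeys(tf_list):  # de-dup, keep order
        if tf not in expr.index:
            rows.append((tf, np.nan, np.nan, "missing", False))
            continue
        try:
            r_e = pearson(expr.loc[tf], e, min_pairs=min_pairs)
            r_m = pearson(expr.loc[tf], m, min_pairs=min_pairs)
        except UndefinedCorrelationError:
            rows.append((tf, np.nan, np.nan, "NA", True))
            continue
        rows.append((tf, r_e, r_m, classify_tier(r_e, r_m), True))
    out = pd.DataFrame(rows, columns=["tf", "r_e", "r_m", "tier", "found"])
    order = {t: i for i, t in enumerate(TIERS)}
    out["_rank"] = out["tier"].map(lambda t: order.get(t, -1))
    out["_sep"] = (out["r_e"] - out["r_m"]).fillna(-np.inf)
    out = out.sort_values(
        ["_rank", "_sep", "tf"], ascending=[False, False, True], kind="mergesort"
    ).drop(columns=["_rank", "_sep"])
    return out.set_index("tf")
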