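"""Reference-peak construction, counting, and gene-level aggregation.

Coordinates are BED-convention throughout: 0-based, half-open [start, end).

The reference peak set for an ATAC experiment is the union of all
per-condition peak calls, with any gap smaller than ``gap_threshold``
(default 100 bp) closed — two merged regions in the output are therefore
always separated by at least the threshold.  Reads are counted per
reference region with bedtools-multicov semantics: an interval overlapping
a region by >= 1 bp increments that region's count, and a fragment
spanning two regions increments both.  Each peak is assigned to the gene
whose transcription start site lies closest to the peak (distance 0 when
the TSS falls inside the peak; strand is ignored for the distance).

CAGE quantification: per-TSS tags-per-million (count / library size x 1e6),
summed over a gene's TSS peaks to give gene-level expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name"]


@dataclass(frozen=True)
class TssRecord:
    gene: str
    chrom: str
    pos: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"TSS position {self.pos} < 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


def _validate_intervals(df: pd.DataFrame, origin: str = "intervals") -> pd.DataFrame:
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"{origin}: missing column {col!r}")
    bad = df.index[~(df["start"] < df["end"]) | (df["start"] < 0)]
    if len(bad):
        raise ValueError(f"{origin}: malformed interval at line {int(bad[0]) + 1}")
    return df


def merge_peaks(
    peak_sets: list[pd.DataFrame], gap_threshold: int = 100
) -> pd.DataFrame:
    """Merge peak sets into a sorted reference, closing sub-threshold gaps.

    Two output regions are joined whenever their gap is strictly smaller
    than ``gap_threshold`` (a gap of exactly the threshold survives).
    Output regions are named ``peak_00000`` ... in coordinate order.
    """
    if gap_threshold < 0:
        raise ValueError("gap_threshold must be >= 0")
    frames = [
        _validate_intervals(df, f"peak set {i}")[["chrom", "start", "end"]]
        for i, df in enumerate(peak_sets)
    ]
    allp = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "end"]
    )
    rows: list[tuple[str, int, int]] = []
    for chrom, sub in allp.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"])
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e or s - cur_e < gap_threshold:  # overlap/abut or small gap
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        rows.append((chrom, cur_s, cur_e))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out["name"] = [f"peak_{i:05d}" for i in range(len(out))]
    return out


def count_in_regions(reads: pd.DataFrame, reference: pd.DataFrame) -> np.ndarray:
    """Count reads overlapping each reference region by >= 1 bp.

    ``reference`` must be sorted and non-overlapping per chromosome
    (merge_peaks output); if not, it is sorted internally with a warning.
    A read spanning several regions increments each of them.  Returns an
    integer vector aligned with ``reference`` rows.
    """
    reference = _validate_intervals(reference, "reference")
    if len(reads):
        _validate_intervals(reads, "reads")
    counts = np.zeros(len(reference), dtype=np.int64)
    ref_by_chrom = {}
    for chrom, sub in reference.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = sub.index.to_numpy()
        order = np.argsort(starts, kind="mergesort")
        if not np.array_equal(order, np.arange(len(order))) or np.any(
            starts[order][1:] < ends[order][:-1]
        ):
            import warnings

            warnings.warn(f"reference not sorted/disjoint on {chrom}; sorting internally")
        ref_by_chrom[chrom] = (starts[order], ends[order], idx[order])
    for chrom, sub in reads.groupby("chrom", sort=False):
        if chrom not in ref_by_chrom:
            continue
        starts, ends, idx = ref_by_chrom[chrom]
        rs = sub["start"].to_numpy()
        re_ = sub["end"].to_numpy()
        lo = np.searchsorted(ends, rs, side="right")  # first region ending after read start
        hi = np.searchsorted(starts, re_, side="left")  # first region starting at/after read end
        # accumulate +1 over idx[lo:hi] via a difference array
        diff = np.zeros(len(starts) + 1, dtype=np.int64)
        valid = hi > lo
        np.add.at(diff, lo[valid], 1)
        np.add.at(diff, hi[valid], -1)
        counts[idx] += np.cumsum(diff[:-1])
    return counts


def count_matrix(
    read_sets: dict[str, pd.DataFrame], reference: pd.DataFrame
) -> pd.DataFrame:
    """Peak x sample count matrix over a shared reference (multicov style)."""
    data = {sample: count_in_regions(reads, reference) for sample, reads in read_sets.items()}
    return pd.DataFrame(data, index=reference["name"].to_numpy())


def closest_gene(
    peak: tuple[str, int, int], tss_records: list[TssRecord]
) -> tuple[str | None, int | None]:
    """Assign a peak to the gene with the nearest TSS.

    Distance is 0 when the TSS lies within [start, end); otherwise the
    base-pair distance from the nearer peak edge (using end-1 as the last
    covered base), signed + when the TSS is downstream of the peak end
    and - when upstream of its start.  Equidistant TSSs resolve to the
    lexicographically smaller gene id.  Returns (None, None) when the
    peak's chromosome has no TSS.
    """
    chrom, start, end = peak
    if not 0 <= start < end:
        raise ValueError(f"malformed peak {peak}")
    best: tuple[int, str, int] | None = None  # (|dist|, gene, signed dist)
    for rec in tss_records:
        if rec.chrom != chrom:
            continue
        if start <= rec.pos < end:
            signed = 0
        elif rec.pos >= end:
            signed = rec.pos - (end - 1)
        else:
            signed = rec.pos - start  # negative
        key = (abs(signed), rec.gene, signed)
        if best is None or key < best:
            best = key
    if best is None:
        return None, None
    return best[1], best[2]


def assign_genes(
    peaks: pd.DataFrame, tss_records: list[TssRecord]
) -> pd.DataFrame:
    """closest_gene applied to every peak row; unassigned peaks keep NaN."""
    genes, dists = [], []
    for row in peaks.itertuples(index=False):
        g, d = closest_gene((row.chrom, int(row.start), int(row.end)), tss_records)
        genes.append(g)
        dists.append(d)
    out = peaks.copy()
    out["gene"] = genes
    out["distance"] = dists
    return out


def cage_gene_expression(
    tss_counts: pd.DataFrame,
    gene_of_tss: pd.Series,
    library_sizes: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-TSS tpm and gene-level expression (sum over a gene's TSS peaks).

    ``tss_counts`` is TSS x sample raw tag counts; ``gene_of_tss`` maps
    TSS id -> gene id.  ``library_sizes`` defaults to the per-sample
    column sums (then each tpm column sums to 1e6).  Returns
    (gene_expression, tss_tpm).
    """
    if library_sizes is None:
        library_sizes = tss_counts.sum(axis=0)
    library_sizes = library_sizes.reindex(tss_counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be > 0 for every sample")
    tpm = tss_counts / library_sizes * 1e6
    genes = gene_of_tss.reindex(tpm.index)
    gene_expr = tpm.groupby(genes).sum().sort_index()
    return gene_expr, tpm


def log_tpm(expr: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(tpm + pseudocount), the display scale for expression panels."""
    return np.log2(expr + pseudocount)
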