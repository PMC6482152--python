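"""Readers and writers for the plain-text interchange formats.

Expression / count / motif matrices travel as TSV with row ids in the
first column; peaks as headerless BED3+name; tracks as CSV with columns
track_id,t,x,y; gene sets as GMT.  Floats are written with repr-level
precision so reruns are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .motility import TRACK_COLUMNS, Track


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_tracks_csv(tracks: list[Track], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        for t, x, y in zip(tr.t, tr.x, tr.y):
            rows.append((tr.track_id, t, x, y))
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 2:
                sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.writelines(g + "\n" for g in genes)


def read_two_column_map(path: str | Path, a: str, b: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in (a, b):
        if col not in df.columns:
            raise ValueError(f"{path}: expected column {col!r}")
    return df[[a, b]]
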