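"""Cell-motility quantification from nuclear tracks.

Tracks come from live-cell imaging (one (t, x, y) record per frame per
nucleus).  Per timepoint t > 0 after re-zeroing to the first observation,

    msd(t) = ((x(t) - x(0))^2 + (y(t) - y(0))^2) / t

i.e. squared displacement from the track origin divided by elapsed time
(units length^2/time).  The per-track summary statistic keeps the maximum
of these values and divides it by the track duration T = t_last - t_first
(units length^2/time^2); group motility is the arithmetic mean of the
per-track statistics.  For a ballistic track of speed v the statistic is
exactly v^2; diffusive motion scores lower at matched RMS step length,
which is what makes the statistic a useful directional-migration readout.

No per-timepoint filtering is applied by default; an optional minimum
track duration can exclude short tracks before summarisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .state import t_test

TRACK_COLUMNS = ["track_id", "t", "x", "y"]


@dataclass
class Track:
    track_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have equal length")
        if self.t.size < 2:
            raise ValueError(f"track {self.track_id!r}: need >= 2 points")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError(f"track {self.track_id!r}: times not strictly increasing")


@dataclass
class MotilitySummary:
    group_id: str
    per_track_stat: dict[str, float]
    n_tracks: int = field(init=False)
    group_msd: float = field(init=False)

    def __post_init__(self) -> None:
        self.n_tracks = len(self.per_track_stat)
        self.group_msd = float(np.mean(list(self.per_track_stat.values())))


def tracks_from_table(table: pd.DataFrame) -> list[Track]:
    """Build Track objects from a long table with columns track_id,t,x,y."""
    missing = [c for c in TRACK_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"track table missing columns {missing}")
    out = []
    for tid, sub in table.groupby("track_id", sort=True):
        sub = sub.sort_values("t")
        out.append(Track(str(tid), sub["t"].values, sub["x"].values, sub["y"].values))
    return out


def msd_curve(track: Track) -> pd.DataFrame:
    """Per-timepoint time-normalised squared displacement.

    Times are re-zeroed to the first observation; the t = 0 point is
    excluded (zero displacement, undefined ratio).  Returns columns
    ``t`` (elapsed) and ``msd``.
    """
    t = track.t - track.t[0]
    dx = track.x - track.x[0]
    dy = track.y - track.y[0]
    msd = (dx[1:] ** 2 + dy[1:] ** 2) / t[1:]
    return pd.DataFrame({"t": t[1:], "msd": msd})


def track_statistic(track: Track) -> float:
    """Max of the msd curve divided by the track duration (>= 0)."""
    curve = msd_curve(track)
    duration = track.t[-1] - track.t[0]
    return float(curve["msd"].max() / duration)


def group_summary(
    tracks: list[Track],
    groups: dict[str, str],
    *,
    min_duration: float | None = None,
) -> tuple[dict[str, MotilitySummary], pd.DataFrame]:
    """Per-group mean of per-track statistics.

    ``groups`` maps track_id -> group label; every labelled group must
    retain at least one track after the optional duration filter.
    Returns ({group -> MotilitySummary}, per-track table).
    """
    by_group: dict[str, dict[str, float]] = {}
    rows = []
    for tr in tracks:
        if tr.track_id not in groups:
            continue
        duration = tr.t[-1] - tr.t[0]
        if min_duration is not None and duration < min_duration:
            continue
        g = groups[tr.track_id]
        stat = track_statistic(tr)
        by_group.setdefault(g, {})[tr.track_id] = stat
        rows.append((tr.track_id, g, duration, stat))
    empty = set(groups.values()) - set(by_group)
    if empty:
        raise KeyError(f"groups with no usable tracks: {sorted(empty)}")
    summaries = {g: MotilitySummary(g, stats) for g, stats in sorted(by_group.items())}
    table = pd.DataFrame(rows, columns=["track_id", "group", "duration", "stat"])
    return summaries, table


def compare_groups(
    summaries: dict[str, MotilitySummary], a: str, b: str
) -> tuple[float, float]:
    """Two-sided Student's t-test between two groups' per-track statistics."""
    return t_test(
        list(summaries[a].per_track_stat.values()),
        list(summaries[b].per_track_stat.values()),
    )
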