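"""Synthetic inputs with the statistical structure the analyses assume.

Three generators emulate the three data modalities the pipeline consumes:

* an expression compendium whose samples sit on a single latent
  epithelial-mesenchymal axis ``u`` (standard normal per sample).
  Epithelial markers load +a.u, mesenchymal markers -a.u (a = 0.9 by
  default), planted MET/EMT transcription factors load ``loading``.u,
  background genes are pure noise; everything rides on a constant
  baseline so values stay nonnegative like array intensities;
* nuclear-tracking tables under ballistic (constant velocity), Brownian
  (i.i.d. Gaussian steps) or persistent-random-walk motion, sampled on a
  regular frame grid t = 0, dt, 2dt, ...;
* ATAC-style peak count matrices: negative-binomial counts around
  per-peak baselines, a Bernoulli peak x motif membership matrix, GC
  content per peak, and optional planted per-group fold changes on the
  peaks carrying a chosen motif.

Each generator is deterministic given its spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import MotifMatch
from .motility import Track


@dataclass(frozen=True)
class EMCompendiumSpec:
    n_samples: int
    n_background_genes: int
    e_markers: tuple[str, ...] = ("CDH1",)
    m_markers: tuple[str, ...] = ("VIM",)
    planted_met_tfs: dict[str, float] = field(default_factory=dict)
    planted_emt_tfs: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.3
    marker_loading: float = 0.9
    baseline: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        names = [*self.e_markers, *self.m_markers, *self.planted_met_tfs, *self.planted_emt_tfs]
        if len(names) != len(set(names)):
            raise ValueError("marker and TF gene lists must be disjoint")
        for tf, loading in {**self.planted_met_tfs, **self.planted_emt_tfs}.items():
            if not -1.0 <= loading <= 1.0:
                raise ValueError(f"loading for {tf!r} outside [-1, 1]")


def simulate_em_compendium(spec: EMCompendiumSpec) -> pd.DataFrame:
    """Gene x sample expression matrix over a latent E-M axis."""
    rng = np.random.default_rng(spec.seed)
    u = rng.standard_normal(spec.n_samples)
    rows: dict[str, np.ndarray] = {}

    def gene(name: str, loading: float) -> None:
        rows[name] = (
            spec.baseline
            + loading * u
            + spec.noise_sd * rng.standard_normal(spec.n_samples)
        )

    for g in spec.e_markers:
        gene(g, spec.marker_loading)
    for g in spec.m_markers:
        gene(g, -spec.marker_loading)
    for g, loading in spec.planted_met_tfs.items():
        gene(g, loading)
    for g, loading in spec.planted_emt_tfs.items():
        gene(g, loading)
    for i in range(spec.n_background_genes):
        gene(f"BG{i:04d}", 0.0)
    samples = [f"S{i:04d}" for i in range(spec.n_samples)]
    return pd.DataFrame(rows, index=samples).T.clip(lower=0.0)


@dataclass(frozen=True)
class TrackSimSpec:
    motion_model: str  # ballistic | brownian | persistent_random_walk
    n_tracks: int
    n_timepoints: int
    dt: float = 0.25  # frame every 15 min, in hours
    speed: float = 1.0  # ballistic, length/time
    step_sd: float = 1.0  # brownian / PRW, length per step
    persistence: float = 0.5  # PRW only, in [0, 1]
    field_size: float = 500.0  # random start positions in [0, field_size]^2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motion_model not in ("ballistic", "brownian", "persistent_random_walk"):
            raise ValueError(f"unknown motion model {self.motion_model!r}")
        if self.n_tracks < 1 or self.n_timepoints < 2:
            raise ValueError("need n_tracks >= 1 and n_timepoints >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.speed < 0 or self.step_sd < 0:
            raise ValueError("speed/step_sd must be >= 0")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must lie in [0, 1]")


def simulate_tracks(spec: TrackSimSpec) -> list[Track]:
    """Cell tracks on the grid t = 0, dt, ..., (n_timepoints-1)*dt."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_timepoints) * spec.dt
    tracks = []
    for i in range(spec.n_tracks):
        x0, y0 = rng.uniform(0.0, spec.field_size, size=2)
        if spec.motion_model == "ballistic":
            theta = rng.uniform(0.0, 2 * np.pi)
            x = x0 + spec.speed * t * np.cos(theta)
            y = y0 + spec.speed * t * np.sin(theta)
        else:
            steps = spec.step_sd * rng.standard_normal((spec.n_timepoints - 1, 2))
            if spec.motion_model == "persistent_random_walk":
                p = spec.persistence
                for k in range(1, len(steps)):
                    steps[k] = p * steps[k - 1] + np.sqrt(1 - p**2) * steps[k]
            pos = np.vstack([[x0, y0], [x0, y0] + np.cumsum(steps, axis=0)])
            x, y = pos[:, 0], pos[:, 1]
        tracks.append(Track(f"track_{i:04d}", t, x, y))
    return tracks


@dataclass(frozen=True)
class PeakSimSpec:
    n_peaks: int
    n_samples: int
    n_motifs: int
    motif_density: float = 0.1
    planted_effects: tuple[tuple[str, str, float], ...] = ()
    baseline_mean: float = 50.0
    dispersion: float = 20.0  # NB size; var = mu + mu^2/dispersion
    peak_mean_shape: float = 4.0  # gamma shape of per-peak baseline spread
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_peaks, self.n_samples, self.n_motifs) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 < self.motif_density < 1.0:
            raise ValueError("motif_density must lie in (0, 1)")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be > 0")
        for motif, _group, fold in self.planted_effects:
            if fold <= 0:
                raise ValueError(f"fold-change for {motif!r} must be > 0")


def sample_groups(spec: PeakSimSpec) -> dict[str, str]:
    """Sample -> group labels: first half 'A', second half 'B'."""
    half = spec.n_samples // 2
    return {
        f"{'A' if i < half else 'B'}_{i:02d}": "A" if i < half else "B"
        for i in range(spec.n_samples)
    }


def simulate_peak_counts(
    spec: PeakSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, MotifMatch]:
    """(peak intervals, peak x sample counts, motif match) triple.

    Counts are negative binomial with per-peak gamma-distributed baseline
    means (overall mean = ``baseline_mean``); a planted effect
    (motif, group, fold) multiplies the mean of that motif's peaks by
    ``fold`` in the group's samples.  ``dispersion`` may be ``np.inf``
    for the Poisson limit.
    """
    rng = np.random.default_rng(spec.seed)
    peak_ids = [f"peak_{i:05d}" for i in range(spec.n_peaks)]
    motif_ids = [f"motif_{i:03d}" for i in range(spec.n_motifs)]
    groups = sample_groups(spec)
    samples = list(groups)

    widths = rng.integers(200, 801, size=spec.n_peaks)
    gaps = rng.integers(200, 2001, size=spec.n_peaks)
    starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(widths[:-1])])
    intervals = pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + widths, "name": peak_ids}
    )

    membership = pd.DataFrame(
        rng.random((spec.n_peaks, spec.n_motifs)) < spec.motif_density,
        index=peak_ids,
        columns=motif_ids,
    )
    gc = pd.Series(rng.uniform(0.3, 0.7, size=spec.n_peaks), index=peak_ids, name="gc")

    peak_mu = rng.gamma(
        spec.peak_mean_shape, spec.baseline_mean / spec.peak_mean_shape, size=spec.n_peaks
    )
    mu = np.tile(peak_mu[:, None], (1, spec.n_samples))
    for motif, group, fold in spec.planted_effects:
        if motif not in membership.columns:
            raise KeyError(f"planted motif {motif!r} not among simulated motifs")
        in_motif = membership[motif].to_numpy()
        in_group = np.array([groups[s] == group for s in samples])
        mu[np.ix_(in_motif, in_group)] *= fold
    if np.isinf(spec.dispersion):
        counts = rng.poisson(mu)
    else:
        p = spec.dispersion / (spec.dispersion + mu)
        counts = rng.negative_binomial(spec.dispersion, p)
    counts = pd.DataFrame(counts, index=peak_ids, columns=samples)
    return intervals, counts, MotifMatch(membership=membership, gc=gc)
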