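import numpy as np
import pandas as pd
import pytest

from metscreen import synthetic


@pytest.fixture(scope="session")
def planted_compendium():
    """Fixed-seed compendium: 3 strong MET-TFs, 3 strong EMT-TFs, 500 nulls."""
    spec = synthetic.EMCompendiumSpec(
        n_samples=500,
        n_background_genes=500,
        planted_met_tfs={"MET_TF1": 0.9, "MET_TF2": 0.85, "MET_TF3": 0.8},
        planted_emt_tfs={"EMT_TF1": -0.9, "EMT_TF2": -0.85, "EMT_TF3": -0.8},
        noise_sd=0.3,
        seed=20240101,
    )
    return spec, synthetic.simulate_em_compendium(spec)


@pytest.fixture(scope="session")
def planted_peaks():
    """Fixed-seed ATAC simulation with a 2-fold motif effect in group B."""
    spec = synthetic.PeakSimSpec(
        n_peaks=2000,
        n_samples=6,
        n_motifs=50,
        motif_density=0.1,
        planted_effects=(("motif_007", "B", 2.0),),
        seed=11,
    )
    intervals, counts, match = synthetic.simulate_peak_counts(spec)
    return spec, intervals, counts, match


def random_intervals(rng: np.random.Generator, n: int, span: int = 2000) -> pd.DataFrame:
    starts = rng.integers(0, span - 1, size=n)
    lengths = rng.integers(1, 200, size=n)
    return pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + lengths}
    )
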