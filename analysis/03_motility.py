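"""Time-adjusted maximum-MSD motility comparison of the track groups.

For every track the maximum of ((x(t)-x(0))^2+(y(t)-y(0))^2)/t is divided
by the track duration; group means are compared with a two-tailed
Student's t-test. Ballistic motion (directional migration, the
mesenchymal phenotype) should dominate Brownian motion at matched RMS
step length. Run 01_simulate_inputs.py first.
"""

from pathlib import Path

import pandas as pd

from metscreen import pipeline

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "analysis"
SEED = 7

if __name__ == "__main__":
    config = pipeline.demo_config(OUTDIR, seed=SEED)
    config["stages"] = ["motility"]
    pipeline.run_pipeline(config)
    groups = pd.read_csv(OUTDIR / "msd_groups.tsv", sep="\t", index_col=0)
    print(groups.round(4).to_string())
    ratio = groups.loc["ballistic", "group_msd"] / groups.loc["brownian", "group_msd"]
    print(f"ballistic/brownian group-MSD ratio: {ratio:.1f}x (see run.log for the t-test)")
    print((OUTDIR / "run.log").read_text().splitlines()[-1])
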