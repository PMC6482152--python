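"""Gene-set state scoring of the reprogramming conditions.

Per-gene Z-scores across the four conditions (Control, OVOL2, TK,
TK+OVOL2; three replicates each) are summarised per E/M/K/F gene set and
tested against Control with two-tailed Student's t-tests. The synthetic
design plants the cooperative pattern: E and K programs up, M and F
programs down, only in TK+OVOL2.
"""

from pathlib import Path

import pandas as pd

from metscreen import pipeline

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "analysis"
SEED = 7

if __name__ == "__main__":
    config = pipeline.demo_config(OUTDIR, seed=SEED)
    config["stages"] = ["state"]
    pipeline.run_pipeline(config)
    pvals = pd.read_csv(OUTDIR / "state_pvals.tsv", sep="\t")
    print(pvals.to_string(index=False))
    hits = pvals[(pvals["condition"] == "TK_OVOL2") & (pvals["p"] < 0.01)]
    print(f"\nsets significantly shifted in TK_OVOL2 vs Control: {sorted(hits['set'])}")
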