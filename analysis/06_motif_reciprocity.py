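"""Motif-accessibility deviations and expression reciprocity.

Computes background-corrected motif deviation Z-scores over the peak
count matrix, labels motifs differentially accessible between groups A
and B under the dual filter (BH q < 0.01 and group-mean z difference
> 5), and classifies the associated TFs as positive or negative
chromatin regulators by comparing the motif change with the expression
change on the same group ordering.
"""

from pathlib import Path

import pandas as pd

from metscreen import pipeline

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "analysis"
SEED = 7

if __name__ == "__main__":
    config = pipeline.demo_config(OUTDIR, seed=SEED)
    config["stages"] = ["motifs"]
    pipeline.run_pipeline(config)
    diff = pd.read_csv(OUTDIR / "motif_differential.tsv", sep="\t", index_col=0)
    labelled = diff[diff["label"] != "ns"]
    print(f"motifs passing the dual filter: {len(labelled)}/{len(diff)}")
    print(labelled[["mean_z_A", "mean_z_B", "q", "label"]].round(4).to_string())
    calls = pd.read_csv(OUTDIR / "reciprocity.tsv", sep="\t")
    classified = calls[~calls["call"].isin(["unclassified", "unmapped"])]
    print("\nreciprocity calls:")
    print(classified.round(3).to_string(index=False))
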