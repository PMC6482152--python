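"""Generate every synthetic input the downstream analyses consume.

Writes an expression compendium with a planted epithelial-mesenchymal
axis, ballistic and Brownian nuclear tracks, and an ATAC-style peak/count/
motif bundle with a planted 2-fold motif-accessibility shift, into
results/analysis/inputs/.
"""

from pathlib import Path

from metscreen import pipeline

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "analysis"
SEED = 7

if __name__ == "__main__":
    config = pipeline.demo_config(OUTDIR, seed=SEED)
    config["stages"] = ["simulate"]
    manifest = pipeline.run_pipeline(config)
    print(f"wrote {len(manifest['artifacts'])} input artifacts to {OUTDIR}/inputs")
    print("compendium: 306 genes x 300 samples on one latent E-M axis")
    print("tracks: 60 ballistic (v=1) + 60 Brownian nuclei, 97 frames at dt=0.25 h")
    print("peaks: 2000 peaks x 6 samples, 50 motifs, motif_007 2-fold up in group B")
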