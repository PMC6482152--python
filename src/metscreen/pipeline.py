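"""End-to-end orchestration of the screening/quantification stages.

A run is driven by a config dict (usually loaded from YAML) with one
block per stage; ``demo_config`` builds an all-synthetic configuration
that exercises every stage at desk scale.  Stages run in dependency
order; each writes plain-text artifacts into the output directory, and
the run ends with a manifest (JSON) listing every artifact with its
SHA-256 checksum plus a resolved copy of the config and a parameter log.
Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import _io, genome, motifs, motility, screen, state, synthetic

STAGE_ORDER = ["simulate", "screen", "motility", "features", "state", "motifs"]

DEFAULT_THRESHOLDS = {
    "gap_threshold": 100,
    "z_threshold": 5.0,
    "q_threshold": 0.01,
    "lfc_threshold": 1.0,
    "pseudocount": 1.0,
    "n_background": 50,
}


def demo_config(outdir: str | Path, seed: int = 0) -> dict:
    """All-synthetic configuration covering every stage."""
    return {
        "seed": int(seed),
        "outdir": str(outdir),
        "stages": list(STAGE_ORDER),
        "thresholds": dict(DEFAULT_THRESHOLDS),
        "simulate": {
            "compendium": {
                "n_samples": 300,
                "n_background_genes": 300,
                "planted_met_tfs": {"MET_TF1": 0.9, "MET_TF2": 0.85, "MET_TF3": 0.8},
                "planted_emt_tfs": {"EMT_TF1": -0.9, "EMT_TF2": -0.85, "EMT_TF3": -0.8},
                "noise_sd": 0.3,
            },
            "tracks": {"n_tracks": 60, "n_timepoints": 97, "dt": 0.25},
            "peaks": {
                "n_peaks": 2000,
                "n_samples": 6,
                "n_motifs": 50,
                "motif_density": 0.1,
                "planted_effects": [["motif_007", "B", 2.0]],
            },
        },
    }


class PipelineError(RuntimeError):
    pass


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(f"stage {stage!r}: required input {path} is missing")
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages; returns the run manifest."""
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    stages = [s for s in STAGE_ORDER if s in config.get("stages", STAGE_ORDER)]
    inputs = outdir / "inputs"
    log: list[str] = [f"seed={seed}", f"stages={stages}"]
    log += [f"threshold {k}={v}" for k, v in sorted(thresholds.items())]

    if "simulate" in stages:
        inputs.mkdir(exist_ok=True)
        sim = config.get("simulate", {})
        comp = sim.get("compendium", {})
        cspec = synthetic.EMCompendiumSpec(
            n_samples=comp.get("n_samples", 300),
            n_background_genes=comp.get("n_background_genes", 300),
            planted_met_tfs=dict(comp.get("planted_met_tfs", {})),
            planted_emt_tfs=dict(comp.get("planted_emt_tfs", {})),
            noise_sd=comp.get("noise_sd", 0.3),
            seed=seed,
        )
        expr = synthetic.simulate_em_compendium(cspec)
        _io.write_matrix_tsv(expr, inputs / "expression.tsv", "gene")
        tfs = [*cspec.planted_met_tfs, *cspec.planted_emt_tfs] + [
            g for g in expr.index if g.startswith("BG")
        ]
        _io.write_gene_list(tfs, inputs / "tfs.txt")
        _io.write_gene_list(list(cspec.e_markers), inputs / "e_candidates.txt")
        _io.write_gene_list(list(cspec.m_markers), inputs / "m_candidates.txt")

        tr = sim.get("tracks", {})
        track_sets, group_map = [], {}
        for model, sub_seed in (("ballistic", seed + 1), ("brownian", seed + 2)):
            spec = synthetic.TrackSimSpec(
                motion_model=model,
                n_tracks=tr.get("n_tracks", 60),
                n_timepoints=tr.get("n_timepoints", 97),
                dt=tr.get("dt", 0.25),
                speed=1.0,
                step_sd=0.5,
                seed=sub_seed,
            )
            for t in synthetic.simulate_tracks(spec):
                t.track_id = f"{model}_{t.track_id}"
                group_map[t.track_id] = model
                track_sets.append(t)
        _io.write_tracks_csv(track_sets, inputs / "tracks.csv")
        pd.Series(group_map, name="group").to_csv(
            inputs / "track_groups.tsv", sep="\t", index_label="track_id"
        )

        pk = sim.get("peaks", {})
        pspec = synthetic.PeakSimSpec(
            n_peaks=pk.get("n_peaks", 2000),
            n_samples=pk.get("n_samples", 6),
            n_motifs=pk.get("n_motifs", 50),
            motif_density=pk.get("motif_density", 0.1),
            planted_effects=tuple(tuple(e) for e in pk.get("planted_effects", [])),
            seed=seed + 3,
        )
        intervals, counts, match = synthetic.simulate_peak_counts(pspec)
        _io.write_bed(intervals, inputs / "peaks.bed")
        _io.write_matrix_tsv(counts, inputs / "peak_counts.tsv", "peak")
        _io.write_matrix_tsv(
            match.membership.astype(int), inputs / "motif_matches.tsv", "peak"
        )
        match.gc.to_frame().to_csv(inputs / "peak_gc.tsv", sep="\t", index_label="peak")
        pd.Series(synthetic.sample_groups(pspec), name="group").to_csv(
            inputs / "atac_groups.tsv", sep="\t", index_label="sample"
        )
        log.append(f"simulate: {expr.shape[0]} genes, {len(track_sets)} tracks, {len(intervals)} peaks")

    if "screen" in stages:
        cfg = config.get("screen", {})
        expr = _io.read_matrix_tsv(
            _require(Path(cfg.get("expr", inputs / "expression.tsv")), "screen")
        )
        tf_list = _io.read_gene_list(Path(cfg.get("tfs", inputs / "tfs.txt")))
        e_cand = _io.read_gene_list(Path(cfg.get("e_candidates", inputs / "e_candidates.txt")))
        m_cand = _io.read_gene_list(Path(cfg.get("m_candidates", inputs / "m_candidates.txt")))
        pair = screen.select_marker_pair(expr, e_cand, m_cand)
        tiers = screen.screen_tfs(expr, tf_list, pair)
        tiers.to_csv(outdir / "screen_tiers.tsv", sep="\t")
        log.append(
            f"screen: pair {pair.e_marker}/{pair.m_marker} r={pair.r_pair:.4f}; "
            f"tiers {tiers['tier'].value_counts().to_dict()}"
        )

    if "motility" in stages:
        cfg = config.get("motility", {})
        table = _io.read_tracks_csv(
            _require(Path(cfg.get("tracks", inputs / "tracks.csv")), "motility")
        )
        groups = (
            pd.read_csv(
                Path(cfg.get("groups", inputs / "track_groups.tsv")), sep="\t", index_col=0
            )["group"]
            .astype(str)
            .to_dict()
        )
        tracks = motility.tracks_from_table(table)
        summaries, per_track = motility.group_summary(tracks, groups)
        per_track.to_csv(outdir / "msd_per_track.tsv", sep="\t", index=False)
        rows = [(g, s.n_tracks, s.group_msd) for g, s in summaries.items()]
        pd.DataFrame(rows, columns=["group", "n_tracks", "group_msd"]).to_csv(
            outdir / "msd_groups.tsv", sep="\t", index=False
        )
        names = sorted(summaries)
        if len(names) == 2:
            t, p = motility.compare_groups(summaries, names[0], names[1])
            log.append(f"motility: {names[0]} vs {names[1]} t={t:.3f} p={p:.3e}")

    if "features" in stages:
        cfg = config.get("features", {})
        peaks = _io.read_bed(_require(Path(cfg.get("peaks", inputs / "peaks.bed")), "features"))
        reference = genome.merge_peaks([peaks], thresholds["gap_threshold"])
        _io.write_bed(reference, outdir / "reference_peaks.bed")
        # TSS annotation: synthetic gene starts along the simulated contig
        import numpy as np

        rng = np.random.default_rng(seed + 4)
        span = int(peaks["end"].max())
        n_genes = int(cfg.get("n_genes", 200))
        tss = [
            genome.TssRecord(f"G{i:04d}", "chr1", int(p), "+" if i % 2 == 0 else "-")
            for i, p in enumerate(sorted(rng.integers(0, span, size=n_genes)))
        ]
        assigned = genome.assign_genes(reference, tss)
        assigned.to_csv(outdir / "peak_genes.tsv", sep="\t", index=False)
        log.append(f"features: {len(reference)} reference peaks, {n_genes} TSS records")

    if "state" in stages:
        cfg = config.get("state", {})
        import numpy as np

        rng = np.random.default_rng(seed + 5)
        conditions = ["Control", "OVOL2", "TK", "TK_OVOL2"]
        reps = int(cfg.get("replicates", 3))
        sets = {
            "E": [f"E{i:03d}" for i in range(40)],
            "M": [f"M{i:03d}" for i in range(40)],
            "K": [f"K{i:03d}" for i in range(40)],
            "F": [f"F{i:03d}" for i in range(40)],
        }
        genes = [g for genes_ in sets.values() for g in genes_] + [
            f"N{i:03d}" for i in range(200)
        ]
        cols, groups = [], {}
        for c in conditions:
            for r in range(reps):
                name = f"{c}_r{r}"
                cols.append(name)
                groups[name] = c
        values = rng.normal(8.0, 1.0, size=(len(genes), len(cols)))
        mat = pd.DataFrame(values, index=genes, columns=cols)
        # the cooperative condition activates E/K programs and shuts M/F down
        shift = {"E": 2.0, "K": 2.0, "M": -2.0, "F": -1.0}
        co = [c for c in cols if groups[c] == "TK_OVOL2"]
        for name, delta in shift.items():
            mat.loc[sets[name], co] += delta
        _io.write_gmt(sets, outdir / "state_sets.gmt")
        zm, _flagged = state.zscore_by_gene(mat)
        result = state.score_gene_sets(zm, sets, "Control", groups=groups)
        result.per_set.to_csv(outdir / "state_scores.tsv", sep="\t", index=False)
        result.pvals.to_csv(outdir / "state_pvals.tsv", sep="\t", index=False)
        _linkage, leaves, _ = state.hcluster(zm.T)
        (outdir / "state_sample_order.txt").write_text("\n".join(leaves) + "\n")
        log.append(f"state: {len(result.pvals)} set/condition tests")

    if "motifs" in stages:
        cfg = config.get("motifs", {})
        counts = _io.read_matrix_tsv(
            _require(Path(cfg.get("counts", inputs / "peak_counts.tsv")), "motifs")
        )
        membership = _io.read_matrix_tsv(
            Path(cfg.get("matches", inputs / "motif_matches.tsv"))
        ).astype(bool)
        gc = pd.read_csv(
            Path(cfg.get("gc", inputs / "peak_gc.tsv")), sep="\t", index_col=0
        )["gc"]
        groups = (
            pd.read_csv(
                Path(cfg.get("groups", inputs / "atac_groups.tsv")), sep="\t", index_col=0
            )["group"]
            .astype(str)
            .to_dict()
        )
        match = motifs.MotifMatch(membership=membership, gc=gc)
        dev = motifs.motif_deviation(
            counts, match, n_background=int(thresholds["n_background"]), seed=seed + 6
        )
        dev.z.to_csv(outdir / "motif_z.tsv", sep="\t", index_label="motif")
        diff = motifs.differential_motifs(
            dev.z, groups, thresholds["z_threshold"], thresholds["q_threshold"]
        )
        diff.to_csv(outdir / "motif_differential.tsv", sep="\t")

        # reciprocity against a synthetic TF expression contrast on the same
        # A/B ordering: planted-motif TFs are induced in group B
        import numpy as np

        rng = np.random.default_rng(seed + 7)
        labelled = diff.index[diff["label"] != motifs.LABEL_NS].tolist()
        tf_genes = {m: f"TF_{m}" for m in diff.index}
        samples = list(counts.columns)
        expr = pd.DataFrame(
            rng.normal(8.0, 0.25, size=(len(diff), len(samples))),
            index=[tf_genes[m] for m in diff.index],
            columns=samples,
        )
        in_b = [s for s in samples if groups[s] == "B"]
        for m in labelled:
            expr.loc[tf_genes[m], in_b] += 16.0  # induced alongside its motif shift
        lfc = motifs.expression_lfc(expr, groups, thresholds["pseudocount"])
        mapping = pd.DataFrame(
            {"motif": list(diff.index), "gene": [tf_genes[m] for m in diff.index]}
        )
        delta = diff["mean_z_B"] - diff["mean_z_A"]
        calls = motifs.reciprocity_classify(
            delta,
            lfc,
            mapping,
            q_threshold=thresholds["q_threshold"],
            lfc_threshold=thresholds["lfc_threshold"],
        )
        calls.to_csv(outdir / "reciprocity.tsv", sep="\t", index=False)
        log.append(
            f"motifs: {len(labelled)} labelled motifs; "
            f"{(calls['call'] != 'unclassified').sum()} reciprocity calls"
        )

    resolved = outdir / "config.resolved.yaml"
    portable = {k: v for k, v in config.items() if k != "outdir"}
    resolved.write_text(
        yaml.safe_dump(
            {**portable, "thresholds": thresholds, "stages": stages}, sort_keys=True
        )
    )
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    artifacts = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": seed,
        "stages": stages,
        "artifacts": {str(p.relative_to(outdir)): _sha256(p) for p in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
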