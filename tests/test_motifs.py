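"""Motif deviation scores, differential filters, BH, reciprocity calls."""

import numpy as np
import pandas as pd
import pytest

from metscreen import synthetic
from metscreen.motifs import (
    LABEL_B,
    LABEL_NS,
    MotifMatch,
    bh_qvalues,
    differential_motifs,
    expression_lfc,
    motif_deviation,
    reciprocity_classify,
)
from metscreen.synthetic import sample_groups


def bh_oracle(p):
    """Naive double-loop BH step-up."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, i in enumerate(order):
        best = 1.0
        for later_pos in range(rank_pos, m):
            j = order[later_pos]
            best = min(best, m * p[j] / (later_pos + 1))
        q[i] = best
    return q


class TestBH:
    def test_hand_worked_example(self):
        assert np.allclose(bh_qvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(bh_qvalues([1.0, 1.0, 1.0]), 1.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(30)
        for _ in range(100):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            q = bh_qvalues(p)
            assert np.allclose(q, bh_oracle(p), atol=1e-12)
            assert (q >= p - 1e-12).all()
            order = np.argsort(p, kind="mergesort")
            assert (np.diff(q[order]) >= -1e-12).all()  # monotone in rank

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.5, 1.5])


class TestMotifDeviation:
    def test_proportional_samples_give_zero(self, planted_peaks):
        _, _, counts, match = planted_peaks
        base = counts.iloc[:, 0].to_numpy(float)
        prop = pd.DataFrame(
            {f"s{i}": base * (i + 1) for i in range(4)}, index=counts.index
        )
        dev = motif_deviation(prop, match, seed=3)
        assert np.nanmax(np.abs(dev.z.to_numpy())) == 0.0

    def test_planted_motif_dominates_group_b(self, planted_peaks):
        spec, _, counts, match = planted_peaks
        groups = sample_groups(spec)
        dev = motif_deviation(counts, match, seed=1)
        b_cols = [s for s in counts.columns if groups[s] == "B"]
        assert dev.z.loc["motif_007", b_cols].mean() > 5
        assert dev.z.abs().max(axis=1).idxmax() == "motif_007"

    def test_consistent_peak_permutation_invariance(self, planted_peaks):
        _, _, counts, match = planted_peaks
        dev = motif_deviation(counts, match, seed=1)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(counts))
        dev_p = motif_deviation(
            counts.iloc[perm],
            MotifMatch(membership=match.membership.iloc[perm], gc=match.gc.iloc[perm]),
            seed=1,
        )
        assert np.allclose(dev.z.to_numpy(), dev_p.z.to_numpy(), equal_nan=True)

    def test_sparse_motifs_flagged(self, planted_peaks):
        _, _, counts, match = planted_peaks
        membership = match.membership.copy()
        membership["rare"] = False
        membership.iloc[:3, -1] = True
        dev = motif_deviation(
            counts, MotifMatch(membership=membership, gc=match.gc), seed=2
        )
        assert "rare" in dev.flagged_motifs

    def test_needs_two_samples(self, planted_peaks):
        _, _, counts, match = planted_peaks
        with pytest.raises(ValueError):
            motif_deviation(counts.iloc[:, :1], match)


class TestDifferentialMotifs:
    def test_identical_groups_unlabelled(self, planted_peaks):
        spec, _, counts, match = planted_peaks
        dev = motif_deviation(counts, match, seed=1)
        z = dev.z.copy()
        z[["B_03", "B_04", "B_05"]] = z[["A_00", "A_01", "A_02"]].to_numpy()
        diff = differential_motifs(z, sample_groups(spec))
        assert (diff["label"] == LABEL_NS).all()

    def test_planted_motif_labelled_in_correct_group(self, planted_peaks):
        spec, _, counts, match = planted_peaks
        dev = motif_deviation(counts, match, seed=1)
        diff = differential_motifs(dev.z, sample_groups(spec))
        assert diff.loc["motif_007", "label"] == LABEL_B
        assert diff.loc["motif_007", "q"] < 0.01
        assert (diff.drop("motif_007")["label"] == LABEL_NS).all()

    def test_single_sample_group_descriptive_only(self, planted_peaks):
        spec, _, counts, match = planted_peaks
        dev = motif_deviation(counts, match, seed=1)
        groups = {"A_00": "A", "B_03": "B", "B_04": "B"}
        diff = differential_motifs(dev.z[list(groups)], groups)
        assert diff["p"].isna().all()
        assert (diff["label"] == LABEL_NS).all()
        assert diff["mean_z_A"].notna().all()


class TestExpressionLfc:
    @staticmethod
    def _groups(cols):
        return {c: c.split("_")[0] for c in cols}

    def test_identical_groups_zero_lfc(self):
        rng = np.random.default_rng(31)
        vals = rng.uniform(1, 100, size=(20, 3))
        expr = pd.DataFrame(
            np.hstack([vals, vals]),
            columns=["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"],
        )
        out = expression_lfc(expr, self._groups(expr.columns))
        assert np.allclose(out["lfc"], 0.0)

    def test_pseudocount_arithmetic(self):
        expr = pd.DataFrame(
            [[8.0, 8.0, 8.0, 2.0, 2.0, 2.0]],
            columns=["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"],
            index=["g"],
        )
        out = expression_lfc(expr, self._groups(expr.columns))
        assert out.loc["g", "lfc"] == pytest.approx(np.log2(3 / 9))
        rev = expression_lfc(expr[::-1], self._groups(expr.columns))
        assert rev.loc["g", "lfc"] == pytest.approx(np.log2(3 / 9))

    def test_planted_fourfold_recovered(self):
        rng = np.random.default_rng(32)
        n = 200
        base = rng.uniform(20, 60, size=n)
        noise = lambda: rng.normal(1.0, 0.05, size=(n, 3))
        A = base[:, None] * noise()
        B = base[:, None] * noise()
        B[:10] *= 4.0
        expr = pd.DataFrame(
            np.hstack([A, B]),
            columns=["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"],
            index=[f"g{i}" for i in range(n)],
        )
        out = expression_lfc(expr, self._groups(expr.columns))
        hits = out.index[(out["q"] < 0.01) & (out["lfc"].abs() > 1)]
        assert set(hits) == {f"g{i}" for i in range(10)}

    def test_all_zero_gene_skipped(self):
        expr = pd.DataFrame(
            [[0.0] * 6, [1, 2, 3, 9, 8, 7]],
            columns=["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"],
            index=["dead", "ok"],
        )
        out = expression_lfc(expr, self._groups(expr.columns))
        assert out.loc["dead", "lfc"] == 0.0
        assert np.isnan(out.loc["dead", "p"])


class TestReciprocity:
    @staticmethod
    def _expr(lfc, q):
        return pd.DataFrame({"lfc": [lfc], "q": [q]}, index=["TF1"])

    @staticmethod
    def _map():
        return pd.DataFrame({"motif": ["m1"], "gene": ["TF1"]})

    def test_ovol2_pattern_negative_regulator(self):
        # expression strongly up while its motif closes
        calls = reciprocity_classify(
            pd.Series({"m1": -8.0}), self._expr(3.0, 1e-4), self._map()
        )
        assert calls["call"].iloc[0] == "negative-regulator"

    def test_tp63_klf4_pattern_positive_regulator(self):
        calls = reciprocity_classify(
            pd.Series({"m1": 8.0}), self._expr(3.0, 1e-4), self._map()
        )
        assert calls["call"].iloc[0] == "positive-regulator"

    def test_subthreshold_expression_unclassified(self):
        for lfc, q in ((3.0, 0.5), (0.5, 1e-4)):
            calls = reciprocity_classify(
                pd.Series({"m1": -8.0}), self._expr(lfc, q), self._map()
            )
            assert calls["call"].iloc[0] == "unclassified"

    def test_unmapped_motif_reported(self):
        calls = reciprocity_classify(
            pd.Series({"mystery": 2.0}), self._expr(3.0, 1e-4), self._map()
        )
        assert calls.loc[calls["motif"] == "mystery", "call"].iloc[0] == "unmapped"

    def test_sign_convention_invariance(self):
        """Flipping the group ordering of BOTH inputs flips nothing."""
        fwd = reciprocity_classify(
            pd.Series({"m1": -8.0}), self._expr(3.0, 1e-4), self._map()
        )
        rev = reciprocity_classify(
            pd.Series({"m1": 8.0}), self._expr(-3.0, 1e-4), self._map()
        )
        assert fwd["call"].iloc[0] == rev["call"].iloc[0] == "negative-regulator"
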