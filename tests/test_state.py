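"""Z-scoring, gene-set state scores, Student's t, hierarchical clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metscreen.state import (
    hcluster,
    score_gene_sets,
    significance_stars,
    spearman_distance_matrix,
    t_test,
    zscore_by_gene,
)


def permutation_pvalue(rng, a, b, n_perm):
    """Monte-Carlo two-sided permutation p for the equal-variance t statistic."""
    na = len(a)
    pooled = np.concatenate([a, b])
    perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    t = stats.ttest_ind(perms[:, :na], perms[:, na:], axis=1, equal_var=True).statistic
    t_obs = stats.ttest_ind(a, b, equal_var=True).statistic
    return float((np.abs(t) >= abs(t_obs)).mean())


class TestZscore:
    def test_simple_row(self):
        m = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]}, index=["g"])
        z, flagged = zscore_by_gene(m)
        assert np.allclose(z.loc["g"], [-1.0, 0.0, 1.0])  # sample sd of (1,2,3) is 1
        assert len(flagged) == 0

    def test_constant_row_flagged_zero(self):
        m = pd.DataFrame({"a": [5.0, 1.0], "b": [5.0, 2.0]}, index=["flat", "ok"])
        z, flagged = zscore_by_gene(m)
        assert (z.loc["flat"] == 0).all()
        assert list(flagged) == ["flat"]

    def test_rows_standardised_exactly(self):
        rng = np.random.default_rng(18)
        m = pd.DataFrame(rng.standard_normal((50, 8)))
        z, _ = zscore_by_gene(m)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(19)
        m = pd.DataFrame(rng.standard_normal((20, 6)))
        scaled = m.mul(rng.uniform(0.5, 4, 20), axis=0).add(
            rng.uniform(-10, 10, 20), axis=0
        )
        z1, _ = zscore_by_gene(m)
        z2, _ = zscore_by_gene(scaled)
        assert np.allclose(z1, z2, atol=1e-10)

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            zscore_by_gene(pd.DataFrame({"only": [1.0, 2.0]}))


class TestTTest:
    def test_equal_samples(self):
        t, p = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_example(self):
        # diff 3, pooled sd 1, se = sqrt(2/3): |t| = 3 / 0.8165 = 3.674
        t, p = t_test([1, 2, 3], [4, 5, 6])
        assert abs(t) == pytest.approx(3.674, abs=0.001)
        assert p == pytest.approx(0.0214, abs=0.001)

    def test_degenerate_variance_raises(self):
        with pytest.raises(ValueError):
            t_test([1.0, 1.0], [2.0, 2.0])

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(20)
        for _ in range(10):
            a = rng.standard_normal(8)
            b = rng.standard_normal(8) + rng.uniform(-1, 1)
            t_obs, p = t_test(a, b)
            p_perm = permutation_pvalue(rng, a, b, n_perm=20000)
            assert p == pytest.approx(
                p_perm, abs=4 * np.sqrt(p_perm * (1 - p_perm) / 20000) + 0.01
            )

    def test_stars(self):
        assert significance_stars(0.5) == ""
        assert significance_stars(0.005) == "*"
        assert significance_stars(1e-6) == "****"


def _null_zmatrix(rng, n_genes=400, reps=3):
    conds = ["Control", "OVOL2", "TK", "TK_OVOL2"]
    cols = [f"{c}_r{r}" for c in conds for r in range(reps)]
    groups = {f"{c}_r{r}": c for c in conds for r in range(reps)}
    mat = pd.DataFrame(
        rng.normal(8, 1, (n_genes, len(cols))),
        index=[f"g{i}" for i in range(n_genes)],
        columns=cols,
    )
    return mat, groups


class TestScoreGeneSets:
    def test_condition_identical_to_control(self):
        rng = np.random.default_rng(22)
        vals = rng.standard_normal((30, 2))
        mat = pd.DataFrame(
            np.hstack([vals, vals]),
            index=[f"g{i}" for i in range(30)],
            columns=["Control_r0", "Control_r1", "X_r0", "X_r1"],
        )
        groups = {"Control_r0": "Control", "Control_r1": "Control",
                  "X_r0": "X", "X_r1": "X"}
        z, _ = zscore_by_gene(mat)
        res = score_gene_sets(z, {"S": list(mat.index)}, "Control", groups=groups)
        assert res.pvals["p"].iloc[0] == pytest.approx(1.0)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(23)
        mat, groups = _null_zmatrix(rng)
        eset = [f"g{i}" for i in range(30)]
        co = [c for c in mat.columns if groups[c] == "TK_OVOL2"]
        mat.loc[eset, co] += 2.0
        z, _ = zscore_by_gene(mat)
        res = score_gene_sets(z, {"E": eset}, "Control", groups=groups)
        row = res.pvals[(res.pvals["set"] == "E") & (res.pvals["condition"] == "TK_OVOL2")]
        assert row["p"].iloc[0] < 0.01
        med = res.per_set.set_index(["set", "condition"])["median"]
        assert med[("E", "TK_OVOL2")] > med[("E", "Control")]

    def test_empty_intersection_warns_not_crashes(self):
        rng = np.random.default_rng(24)
        mat, groups = _null_zmatrix(rng, n_genes=20)
        z, _ = zscore_by_gene(mat)
        with pytest.warns(UserWarning, match="empty intersection"):
            res = score_gene_sets(z, {"ghost": ["nope1", "nope2"]}, "Control", groups=groups)
        assert res.pvals.empty

    def test_tiny_set_scored_but_untested(self):
        rng = np.random.default_rng(25)
        mat, groups = _null_zmatrix(rng, n_genes=20)
        z, _ = zscore_by_gene(mat)
        with pytest.warns(UserWarning, match="test skipped"):
            res = score_gene_sets(z, {"tiny": ["g0", "g1"]}, "Control", groups=groups)
        assert not res.per_set.empty
        assert res.pvals.empty

    def test_overlapping_sets_warn(self):
        rng = np.random.default_rng(26)
        mat, groups = _null_zmatrix(rng, n_genes=20)
        z, _ = zscore_by_gene(mat)
        with pytest.warns(UserWarning, match="overlaps"):
            score_gene_sets(
                z, {"A": ["g0", "g1", "g2"], "B": ["g2", "g3", "g4"]},
                "Control", groups=groups,
            )


def naive_average_linkage(dist: np.ndarray):
    """O(n^3) agglomeration tracking cluster sizes; returns merge heights."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        merged = clusters[i] + clusters[j]
        del clusters[i], clusters[j]
        d = {k: v for k, v in d.items() if i not in k and j not in k}
        for k, members in clusters.items():
            avg = np.mean([dist[a, b] for a in merged for b in members])
            d[(min(k, next_id), max(k, next_id))] = avg
        clusters[next_id] = merged
        next_id += 1
    return heights


class TestHCluster:
    def test_identical_profiles_merge_first(self):
        m = pd.DataFrame(
            [[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]],
            index=["A", "B", "C"],
        )
        linkage, _, _ = hcluster(m)
        assert linkage[0, 2] == pytest.approx(0.0)  # A,B rank-identical
        assert {int(linkage[0, 0]), int(linkage[0, 1])} == {0, 1}

    def test_rank_reversed_item_joins_last(self):
        m = pd.DataFrame(
            [[1, 2, 3], [10, 20, 30], [3, 2, 1]], index=["A", "B", "C"]
        )
        linkage, leaves, _ = hcluster(m)
        assert linkage[-1, 2] == pytest.approx(2.0)
        assert leaves.index("C") in (0, 2)  # C outside the (A,B) pair

    def test_constant_profile_flagged_max_distance(self):
        m = pd.DataFrame([[1, 2, 3], [5, 5, 5]], index=["ok", "flat"])
        dist, constant = spearman_distance_matrix(m)
        assert constant == ["flat"]
        assert dist[0, 1] == 2.0

    def test_merge_heights_match_naive_oracle(self):
        rng = np.random.default_rng(27)
        m = pd.DataFrame(rng.standard_normal((12, 9)))
        dist, _ = spearman_distance_matrix(m)
        linkage, _, _ = hcluster(m)
        expected = naive_average_linkage(dist)
        assert np.allclose(sorted(linkage[:, 2]), sorted(expected), atol=1e-10)

    def test_leaf_order_deterministic(self):
        rng = np.random.default_rng(28)
        m = pd.DataFrame(rng.standard_normal((10, 6)))
        _, leaves1, _ = hcluster(m)
        _, leaves2, _ = hcluster(m.copy())
        assert leaves1 == leaves2
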