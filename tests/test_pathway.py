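"""Batch alignment, normal-tissue standardization and pathway scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from her2seq import pathway, simdata

# per-sample pathway scores from the study's amplified cohort
MUTATED_SCORES = [-0.591, -0.136, -0.593, -0.206]
WILD_SCORES = [0.447, 0.178, -0.037, -0.470, -0.156, -0.485, 0.040]


def frame(values, genes=None, samples=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestAlignBatches:
    def test_matching_moments_is_identity(self):
        rng = np.random.default_rng(0)
        ref = frame(rng.normal(5, 2, (4, 40)))
        pd.testing.assert_frame_equal(pathway.align_batches(ref, ref), ref)

    def test_constant_shift_removed_exactly(self):
        rng = np.random.default_rng(1)
        ref = frame(rng.normal(0, 1, (3, 30)))
        shifted = ref + 3.0
        aligned = pathway.align_batches(shifted, ref)
        pd.testing.assert_frame_equal(aligned, ref, atol=1e-12, rtol=0)

    def test_location_scale_batch_removed_within_3se(self):
        """A simulated (location 2, scale 1.5) batch effect: post-alignment
        per-gene means and variances match the reference within 3 SE."""
        rng = np.random.default_rng(2)
        n_ref, n_tgt = 200, 60
        ref = frame(rng.normal(8, 1.5, (10, n_ref)))
        target = frame(2.0 + 1.5 * rng.normal(8, 1.5, (10, n_tgt)))
        aligned = pathway.align_batches(target, ref)
        se_mean = 1.5 * np.sqrt(1 / n_tgt + 1 / n_ref)
        assert (aligned.mean(axis=1) - ref.mean(axis=1)).abs().max() < 3 * se_mean
        # after alignment the target's per-gene sd equals the reference's
        np.testing.assert_allclose(
            aligned.std(axis=1, ddof=1), ref.std(axis=1, ddof=1), rtol=1e-9
        )

    def test_zero_variance_gene_location_only(self):
        ref = frame([[1.0, 3.0], [10.0, 14.0]])
        target = frame([[5.0, 5.0], [10.0, 14.0]])
        with pytest.warns(UserWarning, match="zero variance"):
            aligned = pathway.align_batches(target, ref)
        np.testing.assert_allclose(aligned.iloc[0], [2.0, 2.0])

    def test_gene_absent_from_reference_passes_through(self):
        ref = frame([[1.0, 3.0]], genes=["g0"])
        target = frame([[4.0, 6.0], [7.0, 9.0]], genes=["g0", "extra"])
        with pytest.warns(UserWarning, match="absent"):
            aligned = pathway.align_batches(target, ref)
        np.testing.assert_allclose(aligned.loc["extra"], [7.0, 9.0])

    def test_no_shared_genes_rejected(self):
        with pytest.raises(ValueError, match="share no genes"):
            pathway.align_batches(
                frame([[1.0, 2.0]], genes=["a"]), frame([[1.0, 2.0]], genes=["b"])
            )


class TestStandardize:
    def test_normals_standardize_to_mean0_sd1(self):
        rng = np.random.default_rng(3)
        normals = frame(rng.normal(7, 3, (5, 40)))
        z = pathway.standardize_to_normals(normals, normals)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, rtol=1e-12)

    def test_value_at_normal_mean_is_zero(self):
        normals = frame([[1.0, 2.0, 3.0]])
        target = frame([[2.0]], samples=["t"])
        z = pathway.standardize_to_normals(target, normals)
        assert z.iloc[0, 0] == 0.0

    def test_hand_computed_example(self):
        """3 genes x 4 samples against a 3-normal reference, checked by
        direct arithmetic."""
        normals = frame(
            [[1.0, 2.0, 3.0], [10.0, 10.0, 16.0], [0.0, 0.0, 0.0]],
            genes=["a", "b", "c"],
        )
        target = frame(
            [[2.0, 4.0, 0.0, 3.0], [13.0, 10.0, 16.0, 7.0], [1.0, 2.0, 3.0, 4.0]],
            genes=["a", "b", "c"],
            samples=list("wxyz"),
        )
        with pytest.warns(UserWarning, match="excluded"):
            z = pathway.standardize_to_normals(target, normals)
        assert "c" not in z.index  # zero normal variance -> excluded
        np.testing.assert_allclose(z.loc["a"], [0.0, 2.0, -2.0, 1.0])
        np.testing.assert_allclose(z.loc["b"], [1.0 / np.sqrt(12), -2.0 / np.sqrt(12), 4.0 / np.sqrt(12), -5.0 / np.sqrt(12)])


class TestPathwayScore:
    def test_all_zero_z_scores_zero(self):
        z = frame(np.zeros((4, 3)), genes=list("abcd"))
        scores = pathway.pathway_score(z, ["a", "b", "c", "d"])
        assert (scores["score"] == 0.0).all()
        assert (scores["n_genes_used"] == 4).all()

    def test_single_gene_set_equals_that_gene(self):
        z = frame([[1.5, -0.5], [9.0, 9.0]], genes=["a", "b"])
        scores = pathway.pathway_score(z, ["a"])
        np.testing.assert_allclose(scores["score"], [1.5, -0.5])

    def test_known_values_equal_hand_mean(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, (10, 2))
        z = frame(vals)
        genes = [f"g{i}" for i in range(10)]
        scores = pathway.pathway_score(z, genes)
        np.testing.assert_allclose(scores["score"], vals.mean(axis=0), rtol=1e-12)

    def test_missing_values_dropped_per_sample(self):
        z = frame([[1.0, np.nan], [3.0, 5.0]], genes=["a", "b"])
        scores = pathway.pathway_score(z, ["a", "b"])
        np.testing.assert_allclose(scores["score"], [2.0, 5.0])
        assert scores["n_genes_used"].tolist() == [2, 1]

    def test_no_overlap_rejected(self):
        z = frame([[1.0]], genes=["a"])
        with pytest.raises(ValueError, match="no gene-set gene"):
            pathway.pathway_score(z, ["zz"])


def enumerate_ranksum_p(a, b) -> float:
    """Independent permutation oracle: exhaustive two-sided rank-sum p."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n = len(a), len(pooled)
    mu = n_a * (n - n_a) / 2

    def u_of(idx):
        return ranks[list(idx)].sum() - n_a * (n_a + 1) / 2

    obs = abs(u_of(range(n_a)) - mu)
    hits = sum(
        1
        for idx in itertools.combinations(range(n), n_a)
        if abs(u_of(idx) - mu) >= obs - 1e-12
    )
    total = sum(1 for _ in itertools.combinations(range(n), n_a))
    return hits / total


class TestCompareGroups:
    def _series(self):
        scores = pd.Series(
            MUTATED_SCORES + WILD_SCORES,
            index=[f"m{i}" for i in range(4)] + [f"w{i}" for i in range(7)],
        )
        labels = pd.Series(
            ["mutated"] * 4 + ["wild"] * 7, index=scores.index
        )
        return scores, labels

    def test_identical_groups_null(self):
        scores = pd.Series([0.1, 0.2, 0.3, 0.1, 0.2, 0.3], index=list("abcdef"))
        labels = pd.Series(["x"] * 3 + ["y"] * 3, index=scores.index)
        res = pathway.compare_groups(scores, labels)
        assert res["welch_t"] == pytest.approx(0.0, abs=1e-12)
        assert res["ranksum_p"] == pytest.approx(1.0)

    def test_study_scores_group_means_and_tests(self):
        """The 4 mutated vs 7 wild amplified samples: group means -0.3815
        and -0.0690; Welch t and exact rank-sum p match independent
        computation (enumeration for the rank-sum)."""
        scores, labels = self._series()
        res = pathway.compare_groups(scores, labels, groups=("mutated", "wild"))
        assert res["group_means"]["mutated"] == pytest.approx(-0.3815, abs=1e-4)
        assert res["group_means"]["wild"] == pytest.approx(-0.0690, abs=1e-4)
        assert res["ranksum_method"] == "exact"
        oracle_p = enumerate_ranksum_p(MUTATED_SCORES, WILD_SCORES)
        assert res["ranksum_p"] == pytest.approx(oracle_p, rel=1e-12)
        assert res["t_p"] == pytest.approx(0.1139, abs=2e-4)

    def test_exact_ranksum_matches_full_enumeration_4v7(self):
        """Package enumeration helper and scipy's exact test agree with
        the independent 330-arrangement oracle on random 4-vs-7 splits."""
        rng = np.random.default_rng(6)
        for _ in range(5):
            a, b = rng.normal(0, 1, 4), rng.normal(0.5, 1, 7)
            oracle = enumerate_ranksum_p(a, b)
            assert pathway.exact_ranksum_p(a, b) == pytest.approx(oracle, rel=1e-12)
            scores = pd.Series(np.concatenate([a, b]))
            labels = pd.Series(["a"] * 4 + ["b"] * 7)
            res = pathway.compare_groups(scores, labels, groups=("a", "b"))
            assert res["ranksum_p"] == pytest.approx(oracle, rel=1e-12)

    def test_small_group_rejected(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        labels = pd.Series(["x", "y", "y"], index=scores.index)
        with pytest.raises(ValueError, match=">= 2"):
            pathway.compare_groups(scores, labels)

    def test_null_pvalues_superuniform(self, pathway_geneset):
        """With no simulated pathway effect the exact rank-sum p-values are
        (super-)uniform: the empirical CDF never exceeds the uniform CDF by
        more than the one-sided KS bound at alpha = 0.01 over 200 seeds."""
        pvals = []
        for seed in range(200):
            expr, annot, normals, _ = simdata.simulate_expression(
                pathway_geneset, pathway_effect=0.0, grb2_extra=0.0,
                batch_shift=(0.0, 1.0), seed=seed,
            )
            z = pathway.standardize_to_normals(expr, normals)
            scores = pathway.pathway_score(z, pathway_geneset)
            res = pathway.compare_groups(
                scores["score"], annot["group"], groups=("mutated", "wild")
            )
            pvals.append(res["ranksum_p"])
        pvals = np.sort(pvals)
        ecdf_exceedance = np.max(np.arange(1, 201) / 200 - pvals)
        assert ecdf_exceedance < 1.52 / np.sqrt(200)  # one-sided KS, alpha=0.01


class TestRankPathwayGenes:
    def test_no_difference_orders_lexicographically(self):
        z = frame(np.zeros((3, 4)), genes=["c", "a", "b"])
        labels = pd.Series(["mutated"] * 2 + ["wild"] * 2, index=z.columns)
        out = pathway.rank_pathway_genes(z, labels, ["c", "a", "b"])
        assert out["gene"].tolist() == ["a", "b", "c"]

    def test_hand_effects_ordering(self):
        z = frame(
            [[-2.0, -2.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 0.0, 0.0]],
            genes=["down", "flat", "up"],
        )
        labels = pd.Series(["mutated"] * 2 + ["wild"] * 2, index=z.columns)
        out = pathway.rank_pathway_genes(z, labels, ["down", "flat", "up"])
        assert out["gene"].tolist() == ["down", "flat", "up"]
        np.testing.assert_allclose(out["effect"], [-2.0, 0.0, 1.0])

    def test_designated_gene_ranks_first_under_extra_effect(self, pathway_geneset):
        """With the default extra down-shift on the GRB2-like gene, it is
        ranked most down-regulated in >= 18 of 20 seeded replicates."""
        first = 0
        for seed in range(20):
            expr, annot, normals, _ = simdata.simulate_expression(
                pathway_geneset, batch_shift=(0.0, 1.0), seed=300 + seed
            )
            z = pathway.standardize_to_normals(expr, normals)
            out = pathway.rank_pathway_genes(z, annot["group"], pathway_geneset)
            first += out.iloc[0]["gene"] == pathway_geneset[0]
        assert first >= 18


class TestCopyNumberExpressionAssoc:
    def test_exact_line(self):
        cn = pd.Series([2.0, 10.0, 20.0, 30.0])
        res = pathway.copy_number_expression_assoc(cn, 0.5 * cn)
        assert res["slope"] == pytest.approx(0.5, rel=1e-12)
        assert res["correlation"] == pytest.approx(1.0, rel=1e-12)

    def test_constant_expression_slope_zero(self):
        cn = pd.Series([2.0, 10.0, 20.0])
        res = pathway.copy_number_expression_assoc(cn, pd.Series([1.0, 1.0, 1.0]))
        assert res["slope"] == 0.0

    def test_noisy_slope_recovered_within_3se(self):
        rng = np.random.default_rng(8)
        cn = pd.Series(rng.uniform(2, 30, 30))
        expr = 1.0 * cn + rng.normal(0, 0.5, 30)
        res = pathway.copy_number_expression_assoc(cn, expr)
        se = 0.5 / (cn.std(ddof=1) * np.sqrt(len(cn)))
        assert res["slope"] == pytest.approx(1.0, abs=3 * se)

    def test_zero_copy_variance_rejected(self):
        cn = pd.Series([5.0, 5.0, 5.0])
        with pytest.raises(ValueError, match="zero variance"):
            pathway.copy_number_expression_assoc(cn, pd.Series([1.0, 2.0, 3.0]))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            pathway.copy_number_expression_assoc(
                pd.Series([1.0, 2.0]), pd.Series([1.0, 2.0])
            )
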