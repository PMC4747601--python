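"""Alpha diversity, sample clustering, and permutation statistics.

Formula implementations are checked against hand evaluation and against
scikit-bio; the permutation t-test against an exhaustive enumeration
oracle built here from scipy's Welch t; complete linkage against an
all-pairs max-rule brute force.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, ttest_ind

from panrecruit import (
    ConfigError,
    alpha_diversity,
    complete_linkage,
    differential_abundance,
    fold_enrichment,
    permutation_fdr,
    permutation_t_test,
    relative_proportions,
)
from panrecruit.stats import pseudo_replicates


class TestAlphaDiversity:
    def test_no_singletons_chao1_equals_richness(self):
        rep = alpha_diversity([5, 3, 2])
        assert rep.s_obs == 3
        assert rep.chao1 == 3.0

    def test_bias_corrected_chao1_hand_value(self):
        # F1=2, F2=1: 3 + 2*1/(2*2) = 3.5
        rep = alpha_diversity([1, 1, 2])
        assert rep.chao1 == pytest.approx(3.5)

    def test_uniform_four_features_analytic(self):
        rep = alpha_diversity([10, 10, 10, 10])
        assert rep.shannon == pytest.approx(np.log(4))
        assert rep.simpson_lambda == pytest.approx(0.25)
        assert rep.gini_simpson == pytest.approx(0.75)

    def test_classic_variant_hand_value_and_f2_zero_error(self):
        # F1=2, F2=1: classic 3 + 4/2 = 5
        assert alpha_diversity([1, 1, 2], "classic").chao1 == pytest.approx(5.0)
        with pytest.raises(ConfigError):
            alpha_diversity([1, 3, 4], "classic")

    def test_matches_scikit_bio_on_random_vectors(self, rng):
        from skbio.diversity.alpha import chao1, dominance, shannon

        for _ in range(20):
            counts = rng.integers(0, 20, size=int(rng.integers(5, 40)))
            if counts.sum() == 0 or (counts > 0).sum() == 0:
                counts[0] = 1
            rep = alpha_diversity(counts)
            assert rep.chao1 == pytest.approx(chao1(counts), abs=1e-12)
            assert rep.shannon == pytest.approx(
                shannon(counts, base=np.e), abs=1e-12
            )
            assert rep.simpson_lambda == pytest.approx(dominance(counts), abs=1e-12)

    def test_chao1_at_least_richness_property(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 5, size=30)
            if (counts > 0).sum() == 0:
                counts[0] = 1
            rep = alpha_diversity(counts)
            assert rep.chao1 >= rep.s_obs - 1e-12

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ConfigError):
            alpha_diversity([0, 0, 0])


class TestRelativeProportions:
    def test_columns_normalize(self):
        df = pd.DataFrame({"a": [2, 2], "b": [0, 5]})
        out = relative_proportions(df)
        assert out["a"].tolist() == [0.5, 0.5]
        assert out["b"].tolist() == [0.0, 1.0]

    def test_any_table_columns_sum_to_one(self, rng):
        df = pd.DataFrame(rng.integers(1, 50, size=(8, 4)))
        out = relative_proportions(df)
        assert np.allclose(out.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_total_sample_error_names_it(self):
        df = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ConfigError, match="empty"):
            relative_proportions(df)


def brute_complete_linkage_cophenetic(dist: np.ndarray) -> np.ndarray:
    """All-pairs max-rule agglomeration; returns the cophenetic matrix."""
    n = dist.shape[0]
    clusters: list[set[int]] = [{i} for i in range(n)]
    coph = np.zeros((n, n))
    d = {frozenset((i, j)): dist[i, j] for i in range(n) for j in range(i + 1, n)}

    def cdist(a: set[int], b: set[int]) -> float:
        return max(dist[i, j] for i in a for j in b)

    while len(clusters) > 1:
        best = min(
            (
                (cdist(clusters[i], clusters[j]), i, j)
                for i in range(len(clusters))
                for j in range(i + 1, len(clusters))
            )
        )
        h, i, j = best
        for a in clusters[i]:
            for b in clusters[j]:
                coph[a, b] = coph[b, a] = h
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return coph


class TestCompleteLinkage:
    def test_identical_samples_merge_at_height_zero(self):
        df = pd.DataFrame({"a": [1, 2, 3], "b": [2, 4, 6], "c": [9, 1, 0]})
        newick = complete_linkage(df)
        assert "(a:0,b:0)" in newick.replace(" ", "")

    def test_forced_topology(self):
        df = pd.DataFrame({"a": [10, 0, 0], "b": [10, 0, 0], "c": [0, 10, 0]})
        newick = complete_linkage(df)
        assert "(a:0,b:0)" in newick  # a and b pair off before c joins

    def test_matches_brute_force_cophenetic(self, rng):
        """Tree tip-to-tip distances equal twice the brute-force complete-
        linkage merge heights on random tables."""
        import io as _io

        from skbio import TreeNode

        df = pd.DataFrame(
            rng.integers(1, 40, size=(10, 5)), columns=list("abcde")
        )
        newick = complete_linkage(df)
        tree = TreeNode.read(_io.StringIO(newick))
        props = relative_proportions(df)
        from scipy.spatial.distance import pdist, squareform

        dist = squareform(pdist(props[list("abcde")].to_numpy().T, "braycurtis"))
        coph = brute_complete_linkage_cophenetic(dist)
        labels = list("abcde")
        for i in range(5):
            for j in range(i + 1, 5):
                got = tree.find(labels[i]).distance(tree.find(labels[j]))
                assert got == pytest.approx(2 * coph[i, j], abs=1e-9)

    def test_single_sample_rejected(self):
        with pytest.raises(ConfigError):
            complete_linkage(pd.DataFrame({"a": [1, 2]}))


def exhaustive_perm_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """p-value by enumerating every group relabeling, Welch t via scipy."""
    pooled = np.concatenate([a, b])
    na = a.size
    t_obs = abs(ttest_ind(a, b, equal_var=False).statistic)
    count = total = 0
    for subset in itertools.combinations(range(pooled.size), na):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(subset)] = True
        t = ttest_ind(pooled[mask], pooled[~mask], equal_var=False).statistic
        total += 1
        if abs(t) >= t_obs - 1e-12:
            count += 1
    return count / total


class TestPermutationTTest:
    def test_identical_groups_give_p_near_one(self):
        x = pd.DataFrame(np.tile([[0.3], [0.7]], (1, 4)))
        res, _ = permutation_t_test(x, x.copy(), n_perm=99)
        assert (res["p_perm"] > 0.9).all()

    def test_strong_separation_hits_exhaustive_floor(self):
        """Means 0.5 vs 0.01 with tiny variance at n=4 vs 4: exhaustive
        8-choose-4 enumeration gives p = 2/70 = 1/35."""
        rng = np.random.default_rng(3)
        a = pd.DataFrame(0.5 + 0.001 * rng.standard_normal((5, 4)))
        b = pd.DataFrame(0.01 + 0.001 * rng.standard_normal((5, 4)))
        res, _ = permutation_t_test(a, b, n_perm=999)
        assert np.allclose(res["p_perm"], 1 / 35)

    def test_matches_exhaustive_oracle_feature_by_feature(self, rng):
        a = pd.DataFrame(rng.random((6, 3)))
        b = pd.DataFrame(rng.random((6, 4)))
        res, _ = permutation_t_test(a, b, n_perm=999)
        for f in range(6):
            oracle_p = exhaustive_perm_oracle(
                a.iloc[f].to_numpy(), b.iloc[f].to_numpy()
            )
            assert res["p_perm"].iloc[f] == pytest.approx(oracle_p)

    def test_constant_feature_statistic_zero_p_one(self):
        a = pd.DataFrame([[0.2, 0.2, 0.2]])
        b = pd.DataFrame([[0.2, 0.2, 0.2]])
        res, _ = permutation_t_test(a, b, n_perm=99)
        assert res["statistic"].iloc[0] == 0.0
        assert res["p_perm"].iloc[0] == 1.0

    def test_null_p_values_approximately_uniform(self):
        """1000 null features: KS distance to uniform below 0.05."""
        rng = np.random.default_rng(12)
        a = pd.DataFrame(rng.random((1000, 5)))
        b = pd.DataFrame(rng.random((1000, 5)))
        res, _ = permutation_t_test(a, b, n_perm=999, seed=5)
        ks = kstest(res["p_perm"], "uniform").statistic
        assert ks < 0.05


class TestPermutationFdr:
    def test_null_dominated_observations_get_q_near_one(self, rng):
        obs = rng.normal(0, 0.5, 50)
        perm = rng.normal(0, 3.0, (50, 200))
        q = permutation_fdr(obs, perm)
        assert (q > 0.9).all()

    def test_monotone_in_statistic_magnitude(self, rng):
        obs = rng.standard_normal(100)
        perm = rng.standard_normal((100, 100))
        q = permutation_fdr(obs, perm)
        order = np.argsort(-np.abs(obs))
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_clear_signal_gets_small_q(self, rng):
        obs = np.concatenate([np.full(5, 10.0), rng.standard_normal(95)])
        perm = rng.standard_normal((100, 500))
        q = permutation_fdr(obs, perm)
        assert (q[:5] < 0.05).all()


class TestFoldEnrichment:
    def test_tenfold_case(self):
        # focal proportion 0.2 vs mean of (0.2, 0.02, 0.02, 0.02, ...)
        df = pd.DataFrame({"focal": [20, 80], "o1": [2, 98], "o2": [2, 98],
                           "o3": [2, 98]})
        fold = fold_enrichment(df, "focal")
        mean = (0.2 + 0.02 * 3) / 4
        assert fold.iloc[0] == pytest.approx(0.2 / mean)

    def test_focal_equal_to_mean_is_one(self):
        df = pd.DataFrame({"a": [1, 3], "b": [1, 3]})
        fold = fold_enrichment(df, "a")
        assert np.allclose(fold, 1.0)

    def test_zero_focal_uses_epsilon_and_stays_below_one(self):
        df = pd.DataFrame({"focal": [0, 100], "other": [30, 70]})
        fold = fold_enrichment(df, "focal")
        assert 0 < fold.iloc[0] < 1


class TestDifferentialAbundance:
    def test_single_samples_expand_to_pseudo_replicates(self, rng):
        counts = rng.integers(10, 500, size=(30, 2))
        df = pd.DataFrame(counts, columns=["trap", "water"])
        res = differential_abundance(df, ["trap"], ["water"], n_perm=99, seed=1)
        assert set(res.columns) == {"statistic", "p_perm", "q_fdr", "fold_enrichment"}
        assert len(res) == 30
        assert ((res["q_fdr"] >= 0) & (res["q_fdr"] <= 1)).all()

    def test_pseudo_replicates_preserve_depth(self, rng):
        col = pd.Series(rng.integers(0, 100, 20), name="s")
        reps = pseudo_replicates(col, k=4, seed=2)
        assert (reps.sum(axis=0) == col.sum()).all()

    def test_planted_difference_detected(self, rng):
        n = 40
        base = rng.integers(50, 200, size=n)
        a = np.column_stack([rng.poisson(base) for _ in range(4)])
        shifted = base.copy()
        shifted[0] *= 20
        b = np.column_stack([rng.poisson(shifted) for _ in range(4)])
        df = pd.DataFrame(
            np.hstack([a, b]),
            columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
        )
        res = differential_abundance(
            df, [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)],
            n_perm=999, seed=3,
        )
        assert res["p_perm"].iloc[0] <= 0.05
        assert res["q_fdr"].iloc[0] <= 0.25
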