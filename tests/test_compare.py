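import numpy as np
import pytest
from scipy.stats import hypergeom

from morphlands import (
    enumerate_weights,
    landscape_group_test,
    pairwise_comparison_matrix,
    permutation_manova,
    top_set,
)
from morphlands.compare import average_top_weights
from morphlands.errors import ValidationError
from morphlands.optimize import GroupFitnessRanking


def make_ranking(fitness, label="g", increment=0.25):
    """Ranking over one-surface-per-candidate dummies with given fitness."""
    n = len(fitness)
    # candidate pool: all weight vectors for some n_surfaces; use distinct unit
    # tuples from an enumeration large enough to cover n candidates
    k = 3
    while len(enumerate_weights(k, increment)) < n:
        k += 1
    vecs = enumerate_weights(k, increment)[:n]
    fitness = np.asarray(fitness, dtype=float)
    units = np.array([wv.units for wv in vecs])
    order = np.lexsort(tuple(units[:, i] for i in range(units.shape[1] - 1, -1, -1)) + (-fitness,))
    return GroupFitnessRanking(
        group_label=label, weight_vectors=vecs, fitness=fitness, order=order
    )


class TestTopSet:
    def test_five_percent_of_100(self):
        rk = make_ranking(np.arange(100.0))
        assert len(top_set(rk, 5)) == 5

    def test_full_percentile(self):
        rk = make_ranking(np.arange(40.0))
        assert len(top_set(rk, 100)) == 40

    def test_large_pool_ceiling_rule(self):
        n = 27405
        rk = make_ranking(np.random.default_rng(0).permutation(n).astype(float))
        assert len(top_set(rk, 5)) == int(np.ceil(0.05 * n)) == 1371

    def test_cutoff_ties_included(self):
        fitness = np.array([5.0, 4.0, 4.0, 4.0, 1.0, 0.0])
        rk = make_ranking(fitness)
        chosen = top_set(rk, 34)  # k = ceil(0.34*6) = 3, but three candidates tie at 4
        assert len(chosen) == 4

    def test_invalid_percentile(self):
        rk = make_ranking(np.arange(10.0))
        with pytest.raises(ValidationError):
            top_set(rk, 0)


class TestLandscapeGroupTest:
    def test_group_against_itself(self):
        fitness = np.random.default_rng(1).normal(size=200)
        ra = make_ranking(fitness, "a")
        rb = make_ranking(fitness.copy(), "b")
        res = landscape_group_test(ra, rb, percentile=5)
        assert res.n_shared == res.size_a == res.size_b
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_top_sets_significant(self):
        n = 1000
        fa = np.arange(float(n))
        fb = -fa  # opposite preferences: top sets disjoint
        res = landscape_group_test(make_ranking(fa, "a"), make_ranking(fb, "b"), percentile=10)
        assert res.n_shared == 0
        assert res.p_value < 0.01

    def test_hypergeometric_matches_permutation_null(self):
        """Closed-form p agrees with an independent 10,000-draw simulation."""
        n, k = 150, 12
        rng = np.random.default_rng(5)
        fa, fb = rng.normal(size=n), rng.normal(size=n)
        ra, rb = make_ranking(fa, "a"), make_ranking(fb, "b")
        res_h = landscape_group_test(ra, rb, percentile=100 * k / n, null_method="hypergeometric")
        res_p = landscape_group_test(
            ra, rb, percentile=100 * k / n, null_method="permutation",
            seed=9, n_permutations=10_000,
        )
        var = hypergeom.cdf(res_h.n_shared, n, res_h.size_a, res_h.size_b)
        se = np.sqrt(var * (1 - var) / 10_000)
        assert abs(res_p.p_value - res_h.p_value) < 3 * se + 1e-4

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        ra = make_ranking(rng.normal(size=120), "a")
        rb = make_ranking(rng.normal(size=120), "b")
        r1 = landscape_group_test(ra, rb)
        r2 = landscape_group_test(rb, ra)
        assert r1.n_shared == r2.n_shared
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_mismatched_pools_rejected(self):
        ra = make_ranking(np.arange(10.0), "a")
        rb = make_ranking(np.arange(12.0), "b")
        with pytest.raises(ValidationError):
            landscape_group_test(ra, rb)


class TestPairwiseMatrix:
    def test_identical_rankings_p_one(self):
        f = np.random.default_rng(2).normal(size=80)
        mat = pairwise_comparison_matrix([make_ranking(f, "a"), make_ranking(f.copy(), "b")])
        assert mat.loc["b", "a"] == pytest.approx(1.0)

    def test_seven_groups_all_pairs(self):
        rng = np.random.default_rng(3)
        ranks = [make_ranking(rng.normal(size=60), f"g{i}") for i in range(7)]
        mat = pairwise_comparison_matrix(ranks)
        upper = np.triu(np.ones((7, 7), dtype=bool), 1)
        assert np.isfinite(mat.to_numpy()[upper]).sum() == 21
        assert np.isfinite(mat.to_numpy()[upper.T]).sum() == 21
        assert np.isnan(np.diag(mat.to_numpy())).all()

    def test_entries_match_single_calls(self):
        rng = np.random.default_rng(4)
        ranks = [make_ranking(rng.normal(size=50), f"g{i}") for i in range(3)]
        mat = pairwise_comparison_matrix(ranks)
        res01 = landscape_group_test(ranks[0], ranks[1])
        assert mat.loc["g0", "g1"] == res01.n_shared
        assert mat.loc["g1", "g0"] == pytest.approx(res01.p_value)

    def test_duplicate_labels_rejected(self):
        f = np.arange(10.0)
        with pytest.raises(ValidationError):
            pairwise_comparison_matrix([make_ranking(f, "x"), make_ranking(f, "x")])


class TestAverageTopWeights:
    def test_tied_plateau_recovers_interior_mean(self):
        """When all candidates tie, the top-set mean is the simplex centroid."""
        rk = make_ranking(np.full(3, 1.0))  # the 3 vectors over increment 0.25? no:
        # make_ranking slices an enumeration; rebuild explicitly for 2 surfaces
        vecs = enumerate_weights(2, 0.5)
        fitness = np.full(3, 1.0)
        units = np.array([wv.units for wv in vecs])
        order = np.lexsort((units[:, 1], units[:, 0], -fitness))
        rk = GroupFitnessRanking("g", vecs, fitness, order)
        avg = average_top_weights(rk, 5)
        assert np.allclose(avg, [0.5, 0.5])


class TestPermutationManova:
    def test_saturated_significance(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.01, (20, 2)), rng.normal(10, 0.01, (20, 2))])
        labels = ["a"] * 20 + ["b"] * 20
        res = permutation_manova(X, labels, n_permutations=499, seed=1)
        assert res.p_value == pytest.approx(1 / 500)
        assert res.r_squared > 0.99

    def test_r2_bounds_and_null_limit(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 2))
        res = permutation_manova(X, ["a", "b", "c"] * 20, n_permutations=99, seed=2)
        assert 0.0 <= res.r_squared <= 1.0
        assert res.p_value >= 1 / 100
        # identical group means in the noiseless limit -> R^2 = 0
        Y = np.tile(np.array([[1.0, 2.0]]), (30, 1))
        res0 = permutation_manova(Y + 0.0, ["a", "b"] * 15, n_permutations=99, seed=3)
        assert res0.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_distance_based_oracle(self):
        """Pseudo-F equals the PERMANOVA identity computed from pairwise distances.

        SS_total = (1/n) sum_{i<j} d_ij^2 and SS_within = sum_g (1/n_g)
        sum_{i<j in g} d_ij^2 — an independent route to the same statistic.
        """
        rng = np.random.default_rng(7)
        X = rng.normal(size=(45, 2))
        labels = np.array(["a"] * 15 + ["b"] * 15 + ["c"] * 15)
        res = permutation_manova(X, labels, n_permutations=99, seed=4)
        from scipy.spatial.distance import pdist, squareform

        D2 = squareform(pdist(X)) ** 2
        n = len(X)
        ss_total = D2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for g in np.unique(labels):
            idx = np.flatnonzero(labels == g)
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_between = ss_total - ss_within
        f_oracle = (ss_between / 2) / (ss_within / (n - 3))
        assert res.f_statistic == pytest.approx(f_oracle, rel=1e-10)
        assert res.r_squared == pytest.approx(ss_between / ss_total, rel=1e-10)

    def test_reproducible_for_seed(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 2))
        labels = ["a", "b"] * 20
        r1 = permutation_manova(X, labels, n_permutations=199, seed=42)
        r2 = permutation_manova(X, labels, n_permutations=199, seed=42)
        assert r1.p_value == r2.p_value

    def test_input_validation(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValidationError):
            permutation_manova(X, ["a", "a", "a", "b"], n_permutations=99)  # group of 1
        with pytest.raises(ValidationError):
            permutation_manova(X, ["a", "a", "b", "b"], n_permutations=10)
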