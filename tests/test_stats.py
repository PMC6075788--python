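"""Permutation nulls, cluster-extent correction, noise ceilings."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from strsa.rdm import RDM, feature_rdm, lower_triangle, n_pairs
from strsa.stats import (
    PermutationNull,
    build_null,
    cluster_extent_correct,
    group_null_stats,
    noise_ceiling,
    noise_ceiling_series,
    pair_permutation_indices,
    permute_rdm_labels,
)


def random_rdm(rng, n=8):
    from tests.test_rdm import make_bank

    return feature_rdm(make_bank(rng.normal(size=(n, 12))))


class TestPermuteLabels:
    def test_identity_is_noop(self, rng):
        rdm = random_rdm(rng)
        out = permute_rdm_labels(rdm, np.arange(8))
        assert np.array_equal(out.values, rdm.values)

    def test_permutation_then_inverse_restores(self, rng):
        rdm = random_rdm(rng)
        perm = rng.permutation(8)
        inv = np.argsort(perm)
        out = permute_rdm_labels(permute_rdm_labels(rdm, perm), inv)
        assert np.allclose(out.values, rdm.values)

    def test_lower_triangle_matches_pair_lookup_oracle(self, rng):
        rdm = random_rdm(rng)
        perm = rng.permutation(8)
        got = lower_triangle(permute_rdm_labels(rdm, perm))
        # brute-force re-lookup of each pair dissimilarity under the relabeling
        expected = []
        for i in range(8):
            for j in range(i):
                expected.append(rdm.values[perm[i], perm[j]])
        assert np.allclose(got, expected)
        assert np.allclose(lower_triangle(rdm)[pair_permutation_indices(8, perm)], expected)

    def test_non_bijective_rejected(self, rng):
        with pytest.raises(ValueError):
            permute_rdm_labels(random_rdm(rng), [0, 0, 1, 2, 3, 4, 5, 6])


@pytest.fixture
def toy_problem(rng):
    n_cat, T, n_sub = 10, 12, 4
    layers = [random_rdm(rng, n_cat) for _ in range(3)]
    neural = [rng.normal(size=(T, n_pairs(n_cat))) + 1.0 for _ in range(n_sub)]
    return neural, layers, n_cat


class TestBuildNull:
    def test_permutation_zero_is_observed(self, toy_problem):
        neural, layers, n_cat = toy_problem
        null = build_null(neural, layers, n_cat, n_permutations=120, seed=3)
        from strsa.encoding import encode_all_layers

        observed = np.mean(
            [[encode_all_layers(sub[t], layers).r2 for t in range(sub.shape[0])]
             for sub in neural],
            axis=0,
        )
        assert np.allclose(null.observed, observed, atol=1e-10)

    def test_deterministic_per_seed(self, toy_problem):
        neural, layers, n_cat = toy_problem
        a = build_null(neural, layers, n_cat, n_permutations=120, seed=5)
        b = build_null(neural, layers, n_cat, n_permutations=120, seed=5)
        assert np.array_equal(a.stats, b.stats)

    def test_small_permutation_count_warns(self, toy_problem):
        neural, layers, n_cat = toy_problem
        with pytest.warns(UserWarning, match="unstable"):
            build_null(neural, layers, n_cat, n_permutations=50, seed=1)

    def test_layer_stat_matches_single_layer_encoder(self, toy_problem):
        neural, layers, n_cat = toy_problem
        from strsa.encoding import encode_single_layer

        nulls = group_null_stats(neural, layers, n_cat, n_permutations=100, seed=2)
        expected = np.mean(
            [[encode_single_layer(sub[t], layers[1]).r2 for t in range(sub.shape[0])]
             for sub in neural],
            axis=0,
        )
        assert np.allclose(nulls["layer"][1][0], expected, atol=1e-10)

    def test_null_distribution_invariant_to_prior_relabeling(self, rng):
        """Relabeling the observed data first leaves the null unchanged in
        distribution (Kolmogorov-Smirnov distance < 0.1)."""
        n_cat = 10
        layers = [random_rdm(rng, n_cat) for _ in range(2)]
        neural = [rng.normal(size=(4, n_pairs(n_cat))) + 1.0 for _ in range(3)]
        perm = rng.permutation(n_cat)
        idx = pair_permutation_indices(n_cat, perm)
        relabeled = [sub[:, idx] for sub in neural]
        a = build_null(neural, layers, n_cat, n_permutations=500, seed=7).stats[1:].ravel()
        b = build_null(relabeled, layers, n_cat, n_permutations=500, seed=8).stats[1:].ravel()
        assert ks_2samp(a, b).statistic < 0.1


class TestClusterExtent:
    def _null_from(self, stats, seed=0):
        return PermutationNull(np.asarray(stats, dtype=float), seed=seed)

    def test_observed_at_null_median_is_empty(self, rng):
        stats = rng.normal(size=(400, 20))
        observed = np.median(stats, axis=0)
        stats[0] = observed
        mask = cluster_extent_correct(observed, self._null_from(stats), 0.05, 1)
        assert not mask.any()

    def test_planted_block_survives_intact(self, rng):
        # null whose max-run quantile is ~5 samples; a 25-sample block survives
        T = 100
        stats = rng.normal(size=(500, T))
        observed = np.zeros(T)
        observed[30:55] = 10.0
        stats[0] = observed
        mask = cluster_extent_correct(observed, self._null_from(stats), 0.05, 1)
        assert mask[30:55].all()
        assert not mask[:30].any() and not mask[55:].any()

    def test_short_blips_removed(self, rng):
        T = 200
        stats = rng.normal(size=(500, T))
        # make long suprathreshold runs common in the null
        for b in range(1, 500):
            start = int(rng.integers(0, T - 40))
            stats[b, start : start + 30] += 5.0
        observed = np.zeros(T)
        observed[50:52] = 10.0
        observed[120:122] = 10.0
        stats[0] = observed
        mask = cluster_extent_correct(observed, self._null_from(stats), 0.05, 1)
        assert not mask.any()

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            cluster_extent_correct(np.zeros(5), PermutationNull(np.zeros((1, 0)), 0), 0.05, 1)


class TestNoiseCeiling:
    def test_identical_participants_reach_one(self, rng):
        v = rng.normal(size=45)
        nc = noise_ceiling(np.tile(v, (5, 1)))
        assert nc.lower[0] == pytest.approx(1.0)
        assert nc.upper[0] == pytest.approx(1.0)

    def test_lower_never_exceeds_upper(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            common = rng.normal(size=66)
            subs = common + rng.normal(size=(5, 66)) * rng.uniform(0.2, 2.0)
            nc = noise_ceiling(subs)
            assert nc.lower[0] <= nc.upper[0] + 1e-12

    def test_two_participants_rejected(self, rng):
        with pytest.raises(ValueError):
            noise_ceiling(rng.normal(size=(2, 30)))

    def test_degenerate_participant_excluded(self, rng):
        subs = rng.normal(size=(4, 30))
        subs[1] = 3.14  # constant
        nc = noise_ceiling(subs)
        assert np.isfinite(nc.lower[0]) and np.isfinite(nc.upper[0])

    def test_series_shape_and_bounds(self, rng):
        common = rng.normal(size=(6, 45))
        arrs = [common + 0.5 * rng.normal(size=(6, 45)) for _ in range(4)]
        nc = noise_ceiling_series(arrs)
        assert nc.lower.shape == (6,)
        assert np.all(nc.lower <= nc.upper + 1e-12)
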