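"""Signed modularity, Louvain, z-Rand, consensus, community maps."""

import numpy as np
import pytest

from stemfc.communities import (Partition, SignedSimilarityNetwork,
                                community_cortical_degree, community_fit,
                                consensus_partition, gamma_sweep,
                                louvain_signed, residualize_against_degree,
                                signed_modularity, similarity_matrix, zrand)
from stemfc.connectome import Connectome
from stemfc.exceptions import DataError, ParameterError

from _oracles import all_set_partitions, signed_modularity_reference


def _net(W):
    W = np.asarray(W, dtype=float)
    return SignedSimilarityNetwork(W)


def _random_signed(rng, n):
    W = rng.uniform(-1, 1, (n, n))
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    return _net(W)


class TestResidualize:
    def test_affine_function_of_pattern_residual_is_zero(self, rng):
        pattern = rng.standard_normal(20)
        block = np.outer(np.full(5, 1.0), 3 + 2 * pattern)
        out = residualize_against_degree(block, pattern)
        assert np.abs(out).max() < 1e-10

    def test_orthogonal_zero_mean_row_unchanged(self, rng):
        pattern = rng.standard_normal(30)
        row = rng.standard_normal(30)
        # orthogonalise against the span of {intercept, pattern}
        e1 = np.ones(30) / np.sqrt(30)
        e2 = pattern - pattern.mean()
        e2 /= np.linalg.norm(e2)
        row -= (row @ e1) * e1 + (row @ e2) * e2
        out = residualize_against_degree(row[None, :], pattern)
        np.testing.assert_allclose(out[0], row, atol=1e-8)

    def test_residuals_orthogonal_to_pattern_and_zero_mean(self, rng):
        pattern = rng.standard_normal(25)
        block = rng.standard_normal((40, 25))
        out = residualize_against_degree(block, pattern)
        assert np.abs(out @ pattern).max() < 1e-8
        assert np.abs(out.mean(axis=1)).max() < 1e-10

    def test_constant_pattern_rejected(self, rng):
        with pytest.raises(DataError):
            residualize_against_degree(rng.standard_normal((3, 5)), np.ones(5))


class TestSimilarityMatrix:
    def test_identical_and_negated_profiles(self):
        block = np.column_stack([[1.0, 2, 3, 4], [1.0, 2, 3, 4], [-1.0, -2, -3, -4]])
        net = similarity_matrix(block, axis="brainstem")
        assert net.W[0, 1] == pytest.approx(1.0)
        assert net.W[0, 2] == pytest.approx(-1.0)
        assert np.all(np.diag(net.W) == 0)

    def test_hand_computed_spearman(self):
        block = np.column_stack([[1.0, 2, 3], [1.0, 3, 2]])
        net = similarity_matrix(block, axis="brainstem")
        assert net.W[0, 1] == pytest.approx(0.5)

    def test_constant_profile_rejected(self):
        block = np.column_stack([[1.0, 1, 1], [1.0, 2, 3]])
        with pytest.raises(DataError):
            similarity_matrix(block, axis="brainstem")


class TestSignedModularity:
    def test_two_dyad_classical_value(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = W[2, 3] = W[3, 2] = 1.0
        q = signed_modularity(_net(W), Partition([1, 1, 2, 2]), 1.0)
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_single_edge_one_community_is_zero(self):
        W = np.zeros((2, 2))
        W[0, 1] = W[1, 0] = 1.0
        q = signed_modularity(_net(W), Partition([1, 1]), 1.0)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_assortative_signed_partition_beats_merged(self):
        W = np.full((6, 6), -0.5)
        W[:3, :3] = 0.9
        W[3:, 3:] = 0.9
        np.fill_diagonal(W, 0.0)
        net = _net(W)
        q_split = signed_modularity(net, Partition([1, 1, 1, 2, 2, 2]), 1.0)
        q_merged = signed_modularity(net, Partition([1] * 6), 1.0)
        assert q_split > q_merged

    def test_matches_double_loop_reference(self, rng):
        for _ in range(10):
            net = _random_signed(rng, 7)
            labels = rng.integers(1, 4, 7)
            q = signed_modularity(net, Partition(labels), 1.7)
            q_ref = signed_modularity_reference(net.W, Partition(labels).labels, 1.7)
            assert q == pytest.approx(q_ref, abs=1e-12)

    def test_invariant_to_relabeling_and_node_permutation(self, rng):
        net = _random_signed(rng, 8)
        labels = rng.integers(1, 4, 8)
        q1 = signed_modularity(net, Partition(labels), 1.0)
        q2 = signed_modularity(net, Partition(labels + 10), 1.0)
        perm = rng.permutation(8)
        q3 = signed_modularity(_net(net.W[np.ix_(perm, perm)]),
                               Partition(labels[perm]), 1.0)
        assert q1 == pytest.approx(q2, abs=1e-12)
        assert q1 == pytest.approx(q3, abs=1e-12)


class TestLouvain:
    def test_recovers_planted_blocks_for_any_seed(self):
        W = np.full((10, 10), -0.5)
        W[:5, :5] = 0.9
        W[5:, 5:] = 0.9
        np.fill_diagonal(W, 0.0)
        net = _net(W)
        for seed in range(10):
            p = louvain_signed(net, 1.0, seed)
            assert p.n_communities == 2
            assert len(set(p.labels[:5])) == 1 and len(set(p.labels[5:])) == 1

    def test_deterministic_under_seed(self, rng):
        net = _random_signed(rng, 20)
        a = louvain_signed(net, 1.0, seed=4)
        b = louvain_signed(net, 1.0, seed=4)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_never_below_trivial_baselines(self, rng):
        for _ in range(10):
            net = _random_signed(rng, 12)
            q = signed_modularity(net, louvain_signed(net, 1.0, 0), 1.0)
            q_single = signed_modularity(net, Partition(np.ones(12, int)), 1.0)
            q_atoms = signed_modularity(net, Partition(np.arange(1, 13)), 1.0)
            assert q >= q_single - 1e-12
            assert q >= q_atoms - 1e-12

    def test_bounded_by_exhaustive_optimum_small_n(self, rng):
        for _ in range(5):
            net = _random_signed(rng, 6)
            best = max(signed_modularity(net, Partition(lab + 1), 1.0)
                       for lab in all_set_partitions(6))
            q = signed_modularity(net, louvain_signed(net, 1.0, 1), 1.0)
            assert q <= best + 1e-9


class TestZrand:
    def test_identical_partitions_attain_own_maximum(self):
        p = Partition([1, 1, 1, 2, 2, 2, 3, 3, 3])
        z_self = zrand(p, p)
        assert z_self > 0
        q = Partition([1, 1, 2, 2, 3, 3, 1, 2, 3])
        assert zrand(p, q) < z_self

    def test_independent_partitions_center_on_zero(self):
        vals = []
        for s in range(1000):
            r = np.random.default_rng(s)
            a = Partition(r.integers(1, 4, 30))
            b = Partition(r.integers(1, 4, 30))
            vals.append(zrand(a, b))
        assert abs(np.nanmean(vals)) < 0.1

    def test_invariant_under_label_permutation(self):
        p = Partition([1, 2, 1, 3, 2, 3, 1, 2])
        q = Partition([2, 1, 2, 3, 1, 3, 2, 1])  # relabeled p
        r = Partition([1, 1, 2, 2, 3, 3, 1, 2])
        assert zrand(p, r) == pytest.approx(zrand(q, r), abs=1e-12)

    def test_degenerate_single_community_is_nan(self):
        assert np.isnan(zrand(Partition([1, 1, 1, 1]), Partition([1, 2, 1, 2])))


class TestConsensus:
    def _planted(self):
        W = np.full((12, 12), -0.4)
        for b in range(3):
            W[4 * b: 4 * b + 4, 4 * b: 4 * b + 4] = 0.8
        np.fill_diagonal(W, 0.0)
        return _net(W)

    def test_unanimous_runs_return_that_partition(self):
        res = consensus_partition(self._planted(), 1.0, n_runs=20, seed=0)
        assert res.partition.n_communities == 3
        assert res.zrand_variance == pytest.approx(0.0, abs=1e-20)

    def test_consensus_is_fixed_point(self):
        net = self._planted()
        res = consensus_partition(net, 1.0, 20, seed=0)
        again = consensus_partition(net, 1.0, 20, seed=99)
        np.testing.assert_array_equal(res.partition.labels, again.partition.labels)

    def test_deterministic_under_seed(self, rng):
        net = _random_signed(rng, 15)
        a = consensus_partition(net, 1.5, 20, seed=3)
        b = consensus_partition(net, 1.5, 20, seed=3)
        np.testing.assert_array_equal(a.partition.labels, b.partition.labels)


class TestGammaSweep:
    def test_default_grid_has_sixty_values(self):
        W = np.full((8, 8), -0.4)
        W[:4, :4] = 0.8
        W[4:, 4:] = 0.8
        np.fill_diagonal(W, 0.0)
        table = gamma_sweep(_net(W), None, n_runs=5, seed=0)
        assert len(table.gamma) == 60
        assert table.gamma[0] == pytest.approx(0.1)
        assert table.gamma[-1] == pytest.approx(6.0)

    def test_resolution_increases_community_count_across_ends(self, rng):
        net = _random_signed(rng, 16)
        table = gamma_sweep(net, np.array([0.1, 6.0]), n_runs=10, seed=1)
        assert table.n_communities[0] <= table.n_communities[-1]


class TestCommunityMaps:
    def _fc(self, rng, n_ctx=6, n_bs=4):
        n = n_ctx + n_bs
        m = rng.uniform(-0.5, 0.5, (n, n))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 1.0)
        classes = ["cortex"] * n_ctx + ["brainstem"] * n_bs
        return Connectome(m, [f"n{i}" for i in range(n)], classes)

    def test_singleton_community_map_equals_fc_column(self, rng):
        fc = self._fc(rng)
        part = Partition([1, 2, 3, 4])
        m = community_cortical_degree(fc, part, 2)
        np.testing.assert_allclose(m.values, fc.matrix[:6, 6 + 1])

    def test_community_maps_sum_to_total_degree(self, rng):
        from stemfc.connectome import weighted_degree
        fc = self._fc(rng)
        part = Partition([1, 2, 1, 2])
        total = weighted_degree(fc, np.arange(6), np.arange(6, 10)).values
        summed = sum(community_cortical_degree(fc, part, c).values
                     for c in (1, 2))
        np.testing.assert_allclose(summed, total, atol=1e-10)

    def test_empty_community_rejected(self, rng):
        with pytest.raises(ParameterError):
            community_cortical_degree(self._fc(rng), Partition([1, 1, 2, 2]), 5)

    def test_profile_equal_to_community_map_gives_unit_fit(self, rng):
        fc = self._fc(rng)
        part = Partition([1, 1, 2, 2])
        cmap = community_cortical_degree(fc, part, 1).values
        residual = rng.standard_normal((6, 4))
        residual[:, 0] = cmap  # node 0's profile equals its community map
        fits = community_fit(residual, part, fc)
        assert fits[0] == pytest.approx(1.0)

    def test_constant_profile_rejected(self, rng):
        fc = self._fc(rng)
        residual = rng.standard_normal((6, 4))
        residual[:, 2] = 0.0
        with pytest.raises(DataError):
            community_fit(residual, Partition([1, 1, 2, 2]), fc)
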