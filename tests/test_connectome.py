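"""FC estimation, group statistics, degree maps, distance profiles, ANOVA."""

import numpy as np
import pytest
from scipy import stats

from stemfc.connectome import (Connectome, class_anova, distance_fc_profile,
                               functional_connectivity, group_average,
                               split_half_reliability, ttest_threshold,
                               weighted_degree)
from stemfc.exceptions import DataError, ParameterError
from stemfc.preprocess import TimeSeriesMatrix


def _ts(values):
    values = np.asarray(values, dtype=float)
    return TimeSeriesMatrix(values, [f"n{i}" for i in range(values.shape[0])])


def _conn(matrix, node_class=None, hemisphere=None):
    n = matrix.shape[0]
    return Connectome(matrix, [f"n{i}" for i in range(n)],
                      node_class or [], hemisphere or [])


class TestFunctionalConnectivity:
    def test_affine_copy_has_unit_correlation(self, rng):
        a = rng.standard_normal(50)
        fc = functional_connectivity(_ts([a, 2 * a + 3]))
        assert fc.matrix[0, 1] == pytest.approx(1.0)

    def test_negated_copy_has_minus_one(self, rng):
        a = rng.standard_normal(50)
        fc = functional_connectivity(_ts([a, -a]))
        assert fc.matrix[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        fc = functional_connectivity(_ts([[1, 2, 3, 4], [1, 2, 4, 3]]))
        assert fc.matrix[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_constant_node_rejected_by_name(self, rng):
        with pytest.raises(DataError, match="n1"):
            functional_connectivity(_ts([rng.standard_normal(10), np.ones(10)]))

    def test_invariant_to_affine_rescaling(self, rng):
        x = rng.standard_normal((4, 60))
        a = functional_connectivity(_ts(x)).matrix
        y = x * rng.uniform(0.5, 3, (4, 1)) + rng.normal(size=(4, 1))
        b = functional_connectivity(_ts(y)).matrix
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestGroupStatistics:
    def test_group_average_is_elementwise_mean(self, rng):
        m1 = np.array([[1.0, 0.2], [0.2, 1.0]])
        m2 = np.array([[1.0, 0.4], [0.4, 1.0]])
        g = group_average([_conn(m1), _conn(m2)])
        assert g.matrix[0, 1] == pytest.approx(0.3)
        np.testing.assert_allclose(g.matrix, g.matrix.T)

    def _cohort(self, rng, edge_values):
        out = []
        for v in edge_values:
            m = np.eye(3)
            m[0, 1] = m[1, 0] = v
            m[0, 2] = m[2, 0] = 0.5 + rng.normal(scale=1e-3)
            m[1, 2] = m[2, 1] = rng.normal(scale=1e-3)
            out.append(_conn(m))
        return out

    def test_consistent_edge_survives_thresholding(self, rng):
        conns = self._cohort(rng, 0.6 + rng.normal(scale=0.01, size=10))
        thr, frac = ttest_threshold(conns, alpha=0.0005)
        assert thr.matrix[0, 1] != 0.0
        assert 0 < frac <= 1

    def test_sign_balanced_edge_is_zeroed(self, rng):
        vals = np.array([0.3, -0.3] * 5) + rng.normal(scale=1e-4, size=10)
        conns = self._cohort(rng, vals)
        thr, _ = ttest_threshold(conns, alpha=0.0005)
        assert thr.matrix[0, 1] == 0.0

    def test_alpha_one_keeps_group_average(self, rng):
        conns = self._cohort(rng, rng.uniform(-0.5, 0.5, 8))
        thr, frac = ttest_threshold(conns, alpha=1.0)
        np.testing.assert_allclose(thr.matrix,
                                   group_average(conns).matrix, atol=1e-12)
        assert frac == 1.0

    def test_perfect_correlation_rejected(self):
        m = np.eye(2)
        m[0, 1] = m[1, 0] = 1.0
        with pytest.raises(DataError, match="Fisher"):
            ttest_threshold([_conn(m)] * 3, alpha=0.05)


class TestWeightedDegree:
    def test_uniform_block(self):
        m = np.full((5, 5), 0.1)
        np.fill_diagonal(m, 1.0)
        deg = weighted_degree(_conn(m), np.array([0]), np.arange(1, 5))
        assert deg.values[0] == pytest.approx(0.4)

    def test_single_target_equals_edge(self, rng):
        m = rng.uniform(-1, 1, (4, 4))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 1.0)
        deg = weighted_degree(_conn(m), np.array([2]), np.array([0]))
        assert deg.values[0] == pytest.approx(m[2, 0])

    def test_self_edges_excluded_when_sets_overlap(self, rng):
        m = np.full((3, 3), 0.2)
        np.fill_diagonal(m, 1.0)
        deg = weighted_degree(_conn(m), np.arange(3), np.arange(3))
        np.testing.assert_allclose(deg.values, 0.4)

    def test_block_flow_conservation(self, rng):
        m = rng.uniform(-1, 1, (7, 7))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 1.0)
        fc = _conn(m)
        a, b = np.arange(3), np.arange(3, 7)
        assert weighted_degree(fc, a, b).values.sum() == pytest.approx(
            weighted_degree(fc, b, a).values.sum(), abs=1e-10)

    def test_empty_target_set_rejected(self, rng):
        with pytest.raises(ParameterError):
            weighted_degree(_conn(np.eye(3)), np.array([0]), np.array([], int))


class TestDistanceProfile:
    def test_exact_monotone_decay_gives_rho_minus_one(self):
        n = 10
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) ** 1.3
        d = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
        m = np.exp(-d / 5)
        fc = _conn(m, node_class=["cortex"] * n)
        prof = distance_fc_profile(fc, coords)
        assert prof["within_cortex"][0] == pytest.approx(-1.0)
        assert np.isnan(prof["within_brainstem"][0])

    def test_null_type_one_error_rate(self, rng):
        """FC independent of distance: p-values uniform, ~5% below 0.05."""
        n = 25
        coords = rng.standard_normal((n, 3)) * 20
        hits = 0
        reps = 400
        for _ in range(reps):
            m = rng.uniform(-1, 1, (n, n))
            m = 0.5 * (m + m.T)
            np.fill_diagonal(m, 1.0)
            fc = _conn(m, node_class=["cortex"] * n)
            p = distance_fc_profile(fc, coords)["within_cortex"][1]
            hits += p < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.03)


class TestSplitHalf:
    def test_identical_subjects_give_perfect_reliability(self, rng):
        m = rng.uniform(-0.5, 0.5, (10, 10))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 1.0)
        classes = ["brainstem"] * 3 + ["cortex"] * 7
        conns = [_conn(m, node_class=classes) for _ in range(8)]
        out = split_half_reliability(conns, n_splits=5, seed=0)
        for key in out:
            np.testing.assert_allclose(out[key], 1.0, atol=1e-12)

    def test_deterministic_under_seed(self, rng):
        classes = ["brainstem"] * 3 + ["cortex"] * 5
        conns = []
        for _ in range(6):
            m = rng.uniform(-0.5, 0.5, (8, 8))
            m = 0.5 * (m + m.T)
            np.fill_diagonal(m, 1.0)
            conns.append(_conn(m, node_class=classes))
        a = split_half_reliability(conns, n_splits=4, seed=7)
        b = split_half_reliability(conns, n_splits=4, seed=7)
        for key in a:
            np.testing.assert_array_equal(a[key], b[key])

    def test_odd_subject_count_rejected(self, rng):
        m = np.eye(4)
        with pytest.raises(ParameterError):
            split_half_reliability([_conn(m)] * 5, 3, 0)


class TestClassAnova:
    def test_two_class_f_equals_squared_t(self, rng):
        vals = rng.standard_normal(30)
        labels = ["a"] * 12 + ["b"] * 18
        f, p, _ = class_anova(vals, labels)
        t, pt = stats.ttest_ind(vals[:12], vals[12:], equal_var=True)
        assert f == pytest.approx(t ** 2, abs=1e-10)
        assert p == pytest.approx(pt, abs=1e-12)

    def test_disjoint_ranges_highly_significant(self, rng):
        vals = np.concatenate([rng.uniform(0, 1, 20), rng.uniform(10, 11, 20)])
        _, p, _ = class_anova(vals, ["lo"] * 20 + ["hi"] * 20)
        assert p < 1e-6

    def test_singleton_class_dropped_with_warning(self, rng):
        vals = rng.standard_normal(21)
        labels = ["a"] * 10 + ["b"] * 10 + ["c"]
        with pytest.warns(UserWarning, match="c"):
            _, _, summaries = class_anova(vals, labels)
        assert set(summaries) == {"a", "b"}
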