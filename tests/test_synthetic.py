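"""Synthetic cohort generator: determinism, planted invariants, fixtures."""

import numpy as np
import pytest

from stemfc.atlas import parcellate_volume, threshold_atlas, count_label_overlap
from stemfc.connectome import functional_connectivity
from stemfc.exceptions import ConfigurationError, ParameterError
from stemfc.synthetic import (generate_cohort, generate_probabilistic_atlas,
                              generate_sphere_coordinates, write_cohort)


class TestSphereCoordinates:
    def test_unit_norm_and_mirrored(self):
        sc = generate_sphere_coordinates(100)
        norms = np.linalg.norm(sc.coords, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)
        left = sc.coords[:100]
        right = sc.coords[100:]
        np.testing.assert_allclose(right, left * [-1, 1, 1], atol=1e-12)

    def test_minimal_set_is_pairwise_distinct(self):
        sc = generate_sphere_coordinates(4)
        assert len(np.unique(sc.coords.round(9), axis=0)) == 8

    def test_quasi_uniform_spacing(self):
        sc = generate_sphere_coordinates(200)
        left = sc.coords[:200]
        d = np.linalg.norm(left[:, None] - left[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        assert nn.std() / nn.mean() < 0.5

    def test_too_few_points_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_sphere_coordinates(3)


class TestCohortStructure:
    def test_identical_seeds_give_bit_identical_cohorts(self):
        kw = dict(n_subjects=2, n_cortex=40, n_brainstem=10, k_communities=3,
                  n_timepoints=80, seed=5)
        a = generate_cohort(**kw)
        b = generate_cohort(**kw)
        for sa, sb in zip(a.subjects, b.subjects):
            assert np.array_equal(sa.values, sb.values)
        assert np.array_equal(a.truth.cortical_projection_maps,
                              b.truth.cortical_projection_maps)

    def test_adding_subjects_preserves_existing_ones(self):
        kw = dict(n_cortex=40, n_brainstem=10, k_communities=3,
                  n_timepoints=80, seed=5)
        small = generate_cohort(n_subjects=2, **kw)
        big = generate_cohort(n_subjects=4, **kw)
        for s in range(2):
            assert np.array_equal(small.subjects[s].values, big.subjects[s].values)

    def test_truth_invariants(self, small_cohort):
        t = small_cohort.truth
        k = t.community_of_brainstem_node.max()
        assert set(np.unique(t.community_of_brainstem_node)) == set(range(1, k + 1))
        np.testing.assert_allclose(t.cortical_projection_maps.mean(axis=1), 0,
                                   atol=1e-8)
        np.testing.assert_allclose(t.cortical_projection_maps.std(axis=1), 1,
                                   atol=1e-8)
        for kk in range(k):
            col = np.abs(t.receptor_coefficients[:, kk])
            top = np.sort(col)[::-1]
            assert top[0] > top[1]

    def test_sphere_coords_unit_and_balanced(self, small_cohort):
        sc = small_cohort.sphere_coords
        np.testing.assert_allclose(np.linalg.norm(sc.coords, axis=1), 1, atol=1e-9)
        hemi = np.array(sc.hemisphere)
        assert (hemi == "L").sum() == (hemi == "R").sum()

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            generate_cohort(n_subjects=1, snr=-1.0)
        with pytest.raises(ConfigurationError):
            generate_cohort(n_subjects=1, n_brainstem=4, k_communities=9)


class TestPlantedSignal:
    def test_noise_free_within_community_fc_exceeds_between(self):
        """With all noise terms off, same-community brainstem pairs correlate
        more strongly than any different-community pair."""
        cohort = generate_cohort(n_subjects=1, n_cortex=40, n_brainstem=12,
                                 k_communities=3, n_timepoints=6000,
                                 snr=1e9, seed=3)
        from stemfc.preprocess import nuisance_regress
        cleaned = nuisance_regress(cohort.subjects[0],
                                   cohort.nuisance_designs[0])
        fc = functional_connectivity(cleaned)
        bs = fc.class_indices("brainstem")
        labels = cohort.truth.community_of_brainstem_node
        block = fc.matrix[np.ix_(bs, bs)]
        same, diff = [], []
        for i in range(len(bs)):
            for j in range(i + 1, len(bs)):
                (same if labels[i] == labels[j] else diff).append(block[i, j])
        assert min(same) > max(diff)

    def test_group_fc_shape_symmetry_diagonal(self, small_cohort):
        fc = functional_connectivity(small_cohort.subjects[0])
        n = small_cohort.n_cortex + small_cohort.n_brainstem
        assert fc.matrix.shape == (n, n)
        np.testing.assert_allclose(fc.matrix, fc.matrix.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(fc.matrix), 1.0, atol=1e-12)

    def test_distance_dependence_weakens_with_short_decay(self):
        from stemfc.connectome import distance_fc_profile, group_average
        rhos = {}
        for decay in (30.0, 1.0):
            cohort = generate_cohort(n_subjects=4, n_cortex=80, n_brainstem=16,
                                     k_communities=3, n_timepoints=210,
                                     distance_decay=decay, seed=9)
            fcs = [functional_connectivity(s) for s in cohort.subjects]
            prof = distance_fc_profile(group_average(fcs), cohort.centroids)
            rhos[decay] = prof["within_cortex"][0]
        assert rhos[30.0] < 0
        assert abs(rhos[1.0]) < abs(rhos[30.0])


class TestProbabilisticAtlasFixture:
    def test_zero_overlap_request_gives_disjoint_masks(self):
        atlas, _ = generate_probabilistic_atlas((20, 20, 20), 6, 0.0, seed=1)
        masks = threshold_atlas(atlas, 0.35)
        hist = count_label_overlap(masks)
        assert set(hist) == {1}

    def test_noiseless_companion_parcel_mean_equals_label_index(self):
        atlas, companion = generate_probabilistic_atlas((20, 20, 20), 6, 0.0,
                                                        seed=1, noise=0.0)
        masks = threshold_atlas(atlas, 0.35)
        out = parcellate_volume(companion, masks)
        for li in range(6):
            np.testing.assert_allclose(out.values[li], li + 1, atol=1e-12)

    def test_requested_overlap_fraction_realised(self):
        atlas, _ = generate_probabilistic_atlas((20, 20, 20), 6, 0.05, seed=1)
        masks = threshold_atlas(atlas, 0.35)
        per_voxel = masks.masks.sum(axis=3)
        labeled = (per_voxel >= 1).sum()
        frac = (per_voxel >= 2).sum() / labeled
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_impossible_placement_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_probabilistic_atlas((6, 6, 6), 50, 0.0, seed=1)


def test_write_cohort_round_trips_key_files(tmp_path, small_cohort):
    out = write_cohort(small_cohort, tmp_path / "cohort")
    import pandas as pd
    sub = pd.read_csv(out / "subject_00.tsv", sep="\t", index_col=0)
    assert sub.shape == (small_cohort.n_cortex + small_cohort.n_brainstem,
                         small_cohort.subjects[0].n_timepoints)
    np.testing.assert_allclose(sub.to_numpy(), small_cohort.subjects[0].values)
    assert (out / "truth.json").exists()
    coords = pd.read_csv(out / "coordinates.tsv", sep="\t")
    assert list(coords.columns) == ["node", "x", "y", "z", "hemisphere", "class"]
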