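"""Generator invariants: mirror geometry, planted truth, count model."""

import numpy as np
import pytest

from tractoica import (
    average_matrices,
    make_geometry,
    plant_components,
    simulate_subject_matrix,
)
from tractoica.synthgeo import expected_rate


class TestGeometry:
    def test_counts_and_involutions(self, geometry):
        assert geometry.n_seeds == 200
        assert geometry.n_targets == 20 * 16 * 16
        n = geometry.n_seeds
        assert np.array_equal(geometry.seed_mirror[geometry.seed_mirror], np.arange(n))
        assert np.array_equal(
            geometry.target_mirror[geometry.target_mirror],
            np.arange(geometry.n_targets),
        )

    def test_mirror_crosses_hemispheres(self, geometry):
        # no fixed points: every left seed pairs with a right seed
        assert np.all(geometry.seed_mirror != np.arange(geometry.n_seeds))
        left = geometry.seed_hemi == "L"
        assert np.all(geometry.seed_hemi[geometry.seed_mirror[left]] == "R")

    def test_right_seeds_are_exact_reflections(self, geometry):
        d0 = geometry.volume_shape[0]
        left = geometry.seed_coords[:100]
        right = geometry.seed_coords[geometry.seed_mirror[:100]]
        assert np.array_equal(right[:, 1:], left[:, 1:])
        assert np.array_equal(right[:, 0], (d0 - 1) - left[:, 0])

    def test_targets_unique_and_in_bounds(self, tiny_geometry):
        tc = tiny_geometry.target_coords
        assert len(np.unique(tc, axis=0)) == tiny_geometry.n_targets
        assert tc.min() >= 0
        assert np.all(tc.max(axis=0) < tiny_geometry.volume_shape)

    def test_minimal_case_pairs_seed_blocks(self):
        g = make_geometry(4, (4, 4, 4), seed=0)
        assert np.array_equal(g.seed_mirror, [4, 5, 6, 7, 0, 1, 2, 3])

    def test_determinism_bit_for_bit(self):
        a = make_geometry(20, (6, 6, 6), seed=7)
        b = make_geometry(20, (6, 6, 6), seed=7)
        assert np.array_equal(a.seed_coords, b.seed_coords)
        assert np.array_equal(a.target_coords, b.target_coords)
        assert np.array_equal(a.seed_mirror, b.seed_mirror)

    @pytest.mark.parametrize(
        "n, shape",
        [(3, (4, 4, 4)), (4, (5, 4, 4)), (4, (4, 3, 4))],
        ids=["too-few-seeds", "odd-mirror-axis", "dim-too-small"],
    )
    def test_rejects_invalid_arguments(self, n, shape):
        with pytest.raises(ValueError):
            make_geometry(n, shape, seed=0)


class TestPlantComponents:
    def test_symmetric_pairs_are_exact_mirrors(self, geometry, truth):
        assert len(truth.symmetric_pairs) == 4
        for a, b in truth.symmetric_pairs:
            assert np.array_equal(
                truth.grey_truth[:, b], truth.grey_truth[geometry.seed_mirror, a]
            )
            assert np.array_equal(
                truth.white_truth[:, b], truth.white_truth[geometry.target_mirror, a]
            )

    def test_every_column_has_positive_support(self, truth):
        assert np.all(truth.grey_truth.max(axis=0) > 0)
        assert np.all(truth.white_truth.max(axis=0) > 0)
        assert np.all(truth.grey_truth >= 0)
        assert np.all(truth.white_truth >= 0)

    def test_zero_overlap_gives_disjoint_supports(self, truth):
        support = truth.grey_truth > 0
        for i in range(truth.k_true):
            for j in range(i + 1, truth.k_true):
                # mirror partners live on opposite hemispheres, so all
                # pairs must be disjoint at overlap=0
                assert not np.any(support[:, i] & support[:, j])

    def test_overlap_controls_adjacent_jaccard(self, geometry):
        t = plant_components(geometry, k_true=8, overlap=0.3, symmetric=True, seed=5)
        support = t.grey_truth > 0
        # within each hemisphere, components are laid out along an axis;
        # neighbouring supports should share the requested Jaccard overlap
        jacc = []
        for hemi_cols in ([0, 1, 2, 3], [4, 5, 6, 7]):
            for i, j in zip(hemi_cols, hemi_cols[1:]):
                inter = np.sum(support[:, i] & support[:, j])
                union = np.sum(support[:, i] | support[:, j])
                jacc.append(inter / union)
        assert abs(np.mean(jacc) - 0.3) <= 0.1

    def test_winner_truth_is_argmax_with_sentinel(self, truth):
        in_sup = truth.grey_truth.max(axis=1) > 0
        assert np.array_equal(
            truth.winner_truth[in_sup], np.argmax(truth.grey_truth[in_sup], axis=1)
        )
        assert np.all(truth.winner_truth[~in_sup] == -1)

    def test_two_disjoint_components_give_two_winner_values(self, geometry):
        t = plant_components(geometry, k_true=2, overlap=0.0, symmetric=False, seed=3)
        winners = t.winner_truth[t.winner_truth >= 0]
        assert set(winners) == {0, 1}

    def test_rejects_bad_arguments(self, tiny_geometry):
        with pytest.raises(ValueError):
            plant_components(tiny_geometry, k_true=3, overlap=0.0, symmetric=True, seed=0)
        with pytest.raises(ValueError):
            plant_components(tiny_geometry, k_true=40, overlap=0.0, symmetric=False, seed=0)


class TestSimulation:
    def test_counts_bounded_by_streamline_budget(self, geometry, truth):
        m = simulate_subject_matrix(truth, geometry, n_samples_per_seed=10_000, seed=1)
        assert m.counts.min() >= 0
        assert m.counts.max() <= 10_000

    def test_zero_baseline_restricts_support(self, tiny_geometry):
        t = plant_components(
            tiny_geometry, k_true=1, overlap=0.0, symmetric=False, seed=4,
            baseline_rate=0.0,
        )
        m = simulate_subject_matrix(t, tiny_geometry, noise_scale=0.0, seed=5)
        outside = np.outer(t.grey_truth[:, 0] == 0, np.ones(tiny_geometry.n_targets, bool)) | \
            np.outer(np.ones(tiny_geometry.n_seeds, bool), t.white_truth[:, 0] == 0)
        assert np.all(m.counts[outside] == 0)

    def test_empirical_mean_matches_poisson_rate(self, tiny_geometry):
        t = plant_components(tiny_geometry, k_true=2, overlap=0.0, symmetric=True, seed=6)
        rate = expected_rate(t, tiny_geometry, 1000)
        reps = np.stack(
            [
                simulate_subject_matrix(
                    t, tiny_geometry, n_samples_per_seed=1000, seed=s
                ).counts
                for s in range(60)
            ]
        )
        se = np.sqrt(rate / reps.shape[0])
        dev = np.abs(reps.mean(axis=0) - rate)
        # zero-rate cells must be exactly zero
        assert np.all(dev[rate == 0] == 0)
        # per-cell 3-SE check, allowing the ~0.3% of cells that pure
        # Poisson chance puts beyond 3 sigma
        within = dev[rate > 0] <= 3 * se[rate > 0]
        assert within.mean() >= 0.99
        # standardized deviations should collectively look standard normal
        z = dev[rate > 0] / se[rate > 0]
        assert np.sqrt(np.mean(z**2)) <= 1.2

    def test_determinism(self, tiny_geometry):
        t = plant_components(tiny_geometry, k_true=2, overlap=0.0, symmetric=True, seed=6)
        a = simulate_subject_matrix(t, tiny_geometry, seed=9)
        b = simulate_subject_matrix(t, tiny_geometry, seed=9)
        assert np.array_equal(a.counts, b.counts)

    def test_rejects_negative_noise(self, tiny_geometry):
        t = plant_components(tiny_geometry, k_true=2, overlap=0.0, symmetric=True, seed=6)
        with pytest.raises(ValueError):
            simulate_subject_matrix(t, tiny_geometry, noise_scale=-0.1, seed=0)


class TestAveraging:
    def test_identity_and_idempotence(self, tiny_geometry):
        t = plant_components(tiny_geometry, k_true=2, overlap=0.0, symmetric=True, seed=6)
        m = simulate_subject_matrix(t, tiny_geometry, seed=11)
        assert np.array_equal(average_matrices([m]).counts, m.counts)
        assert np.array_equal(average_matrices([m, m]).counts, m.counts)

    def test_elementwise_mean(self, tiny_geometry):
        t = plant_components(tiny_geometry, k_true=2, overlap=0.0, symmetric=True, seed=6)
        m1 = simulate_subject_matrix(t, tiny_geometry, seed=1)
        m2 = simulate_subject_matrix(t, tiny_geometry, seed=2)
        avg = average_matrices([m1, m2])
        assert np.allclose(avg.counts, (m1.counts + m2.counts) / 2)
        assert avg.subject_id == "group-average"
        assert avg.n_samples_per_seed == m1.n_samples_per_seed

    def test_rejects_empty_and_mismatched(self, tiny_geometry, geometry, truth):
        with pytest.raises(ValueError):
            average_matrices([])
        t = plant_components(tiny_geometry, k_true=2, overlap=0.0, symmetric=True, seed=6)
        small = simulate_subject_matrix(t, tiny_geometry, seed=1)
        big = simulate_subject_matrix(truth, geometry, seed=1)
        with pytest.raises(ValueError):
            average_matrices([small, big])
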