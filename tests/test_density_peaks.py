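"""Density-peaks clustering: literal formula cases, tie-break conventions,
and exact agreement with a naive double-loop reference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldadp.density_peaks import (
    assign_labels,
    cutoff_distance,
    delta_neighbor,
    dp_cluster,
    dp_index,
    local_density,
    pairwise_distances,
    select_centers,
)
from reference_dp import reference_dp


class TestPairwiseDistances:
    def test_squared_convention(self):
        D = pairwise_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert D[0, 1] == 25.0  # squared Euclidean, no root

    def test_euclidean_option(self):
        D = pairwise_distances(np.array([[0.0, 0.0], [3.0, 4.0]]), metric="euclidean")
        assert D[0, 1] == 5.0

    def test_coincident_points_and_symmetry(self, rng):
        Y = rng.standard_normal((10, 3))
        Y[3] = Y[7]
        D = pairwise_distances(Y)
        assert D[3, 7] == 0.0
        assert np.array_equal(D, D.T)
        assert np.all(np.diag(D) == 0.0)


class TestCutoffDistance:
    def test_rank_on_pair_list(self, rng):
        Y = rng.standard_normal((20, 3))
        D = pairwise_distances(Y)
        d_sort = np.sort(D[np.triu_indices(20, k=1)])
        # M = 190 pairs, round(190 * 0.02) = 4 -> 4th smallest
        assert cutoff_distance(D, 0.02) == d_sort[3]

    def test_scaling_homogeneity(self, rng):
        Y = rng.standard_normal((15, 3))
        D = pairwise_distances(Y)
        D9 = pairwise_distances(3.0 * Y)
        assert np.isclose(cutoff_distance(D9, 0.015), 9.0 * cutoff_distance(D, 0.015))

    def test_rank_clamps_to_smallest(self, rng):
        Y = rng.standard_normal((5, 2))
        D = pairwise_distances(Y)
        d_sort = np.sort(D[np.triu_indices(5, k=1)])
        with pytest.warns(UserWarning):
            assert cutoff_distance(D, 0.0101 / 10) == d_sort[0]

    def test_points_basis_option(self, rng):
        Y = rng.standard_normal((200, 3))
        D = pairwise_distances(Y)
        d_sort = np.sort(D[np.triu_indices(200, k=1)])
        assert cutoff_distance(D, 0.015, rank_basis="points") == d_sort[2]  # round(200*.015)=3


class TestLocalDensity:
    def test_two_points_at_cutoff(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        rho = local_density(D, dc=1.0)
        assert np.allclose(rho, np.exp(-1.0) - 1.0)

    def test_coincident_points(self):
        n = 6
        rho = local_density(np.zeros((n, n)), dc=0.5)
        assert np.allclose(rho, n - 2.0)

    def test_shift_does_not_change_ordering(self, rng):
        Y = rng.standard_normal((30, 3))
        D = pairwise_distances(Y)
        dc = cutoff_distance(D, 0.015)
        rho = local_density(D, dc)
        unshifted = np.exp(-((D / dc) ** 2)).sum(axis=1)
        assert np.array_equal(np.argsort(rho, kind="stable"), np.argsort(unshifted, kind="stable"))

    def test_rejects_nonpositive_cutoff(self):
        with pytest.raises(ValueError):
            local_density(np.zeros((3, 3)), dc=0.0)


class TestDeltaNeighbor:
    def test_hand_case_squared(self):
        # 1-D points {0,1,3}; densities 3 > 2 > 1
        D = pairwise_distances(np.array([[0.0], [1.0], [3.0]]))
        rho = np.array([3.0, 2.0, 1.0])
        delta, n_up = delta_neighbor(D, rho)
        assert delta[0] == 9.0 and n_up[0] == 0  # density max: farthest point
        assert delta[1] == 1.0 and n_up[1] == 0
        assert delta[2] == 4.0 and n_up[2] == 1  # min(9, 4) squared distances

    def test_density_max_points_to_itself(self, rng):
        Y = rng.standard_normal((12, 3))
        D = pairwise_distances(Y)
        rho = local_density(D, cutoff_distance(D, 0.015))
        _, n_up = delta_neighbor(D, rho)
        top = np.lexsort((np.arange(12), -rho))[0]
        assert n_up[top] == top
        assert np.sum(n_up == np.arange(12)) == 1


class TestDpIndexAndCenters:
    def test_elementwise_product(self):
        assert np.array_equal(dp_index(np.array([2.0, 0.0]), np.array([3.0, 7.0])), [6.0, 0.0])

    def test_k_largest(self):
        lam = np.array([5.0, 1.0, 4.0, 9.0])
        assert set(select_centers(lam, 2)) == {3, 0}
        assert list(select_centers(lam, 2)) == [3, 0]  # decreasing-lambda order

    def test_tie_broken_by_density(self):
        lam = np.array([4.0, 4.0, 1.0])
        rho = np.array([1.0, 2.0, 5.0])
        assert select_centers(lam, 1, rho)[0] == 1

    def test_all_points_centers_when_k_equals_n(self, rng):
        Y = rng.standard_normal((5, 2))
        labels, state = dp_cluster(Y, t=0.015, K=5)
        assert sorted(labels) == [1, 2, 3, 4, 5]


class TestAssignLabels:
    def test_chain_propagation(self):
        # chain 2 -> 1 -> 0, only 0 is a center
        rho = np.array([3.0, 2.0, 1.0])
        n_up = np.array([0, 0, 1])
        labels = assign_labels(rho, n_up, centers=np.array([0]))
        assert np.array_equal(labels, [1, 1, 1])

    def test_centers_keep_own_labels(self, three_blobs):
        Y, _, _ = three_blobs
        labels, state = dp_cluster(Y, t=0.015, K=3)
        for rank, c in enumerate(state.centers, start=1):
            assert labels[c] == rank


class TestOracleEquivalence:
    def test_exact_match_on_random_instances(self):
        """Every DPState field and the labels match a naive double-loop
        reference exactly, over 100 random small instances."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 13))
            K = int(rng.integers(2, min(n, 5)))
            Y = rng.standard_normal((n, 3))
            labels, state = dp_cluster(Y, t=0.015, K=K)
            ref_labels, D, dc, rho, delta, n_up, lam, centers = reference_dp(Y, 0.015, K)
            assert np.array_equal(state.D, D)
            assert state.dc == dc
            assert np.array_equal(state.rho, rho)
            assert np.array_equal(state.delta, delta)
            assert np.array_equal(state.n_up, n_up)
            assert np.array_equal(state.lam, lam)
            assert np.array_equal(state.centers, centers)
            assert np.array_equal(labels, ref_labels)

    def test_blob_recovery_and_determinism(self, three_blobs):
        Y, truth, _ = three_blobs
        labels1, _ = dp_cluster(Y, t=0.015, K=3)
        labels2, _ = dp_cluster(Y, t=0.015, K=3)
        assert np.array_equal(labels1, labels2)
        # partition identical to ground truth up to label permutation
        from ldadp.metrics import sorting_accuracy

        assert sorting_accuracy(labels1, truth) == 1.0

    def test_exactly_k_labels(self, rng):
        Y = rng.standard_normal((40, 3))
        labels, _ = dp_cluster(Y, t=0.015, K=4)
        assert set(labels) == {1, 2, 3, 4}


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_center_index_dominates_noncenters(seed):
    """After tie-break ordering, every selected center has a DP index at
    least as large as every non-center."""
    rng = np.random.default_rng(seed)
    Y = rng.standard_normal((15, 3))
    _, state = dp_cluster(Y, t=0.015, K=3)
    non_centers = np.setdiff1d(np.arange(15), state.centers)
    assert state.lam[state.centers].min() >= state.lam[non_centers].max() or np.isclose(
        state.lam[state.centers].min(), state.lam[non_centers].max()
    )
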