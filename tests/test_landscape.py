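"""Clustering, transition counting, min-cut barriers, TRDG, roughness."""

import itertools

import numpy as np
import pytest

from nstarkit.fixtures import ToyLandscapeSpec, simulate_toy_markov
from nstarkit.landscape import (DisconnectivityTree, TransitionNetwork,
                                annotate_states, build_trdg,
                                cluster_trajectories, count_transitions,
                                knee_point, mincut_barrier, pairwise_mincut,
                                roughness_profile)


def network(counts, kbt=1.0, states=None, dt=None):
    counts = np.asarray(counts, dtype=float)
    if states is None:
        states = np.arange(1, counts.shape[0] + 1)
    return TransitionNetwork(states=np.asarray(states), counts=counts,
                             lag=1, kbt=kbt, dt_frame_ps=dt)


def brute_force_mincut(net, A, B):
    """Minimum over all 2-partitions separating A from B."""
    idx_A = {net.index_of(a) for a in A}
    idx_B = {net.index_of(b) for b in B}
    rest = [i for i in range(net.n_states) if i not in idx_A | idx_B]
    s = net.sym_counts
    cap = s + s.T  # undirected edge capacity n_ij + n_ji
    best = np.inf
    for assignment in itertools.product([0, 1], repeat=len(rest)):
        side_a = set(idx_A) | {r for r, side in zip(rest, assignment)
                               if side == 0}
        value = sum(cap[i, j] for i in side_a
                    for j in range(net.n_states) if j not in side_a) / 1.0
        best = min(best, value)
    return best


class TestClustering:
    def test_knee_at_three_blobs(self):
        rng = np.random.default_rng(0)
        centers = 10.0 * np.eye(3)
        X = np.vstack([c + rng.normal(0, 0.5, (80, 3)) for c in centers])
        model = cluster_trajectories(None, k_range=range(1, 9), seed=0,
                                     features=[X])
        assert model.k == 3

    def test_single_repeated_frame_gives_k1(self):
        X = np.ones((50, 4))
        with pytest.warns(UserWarning, match="identical"):
            model = cluster_trajectories(None, k_range=range(1, 5),
                                         features=[X])
        assert model.k == 1
        assert np.all(model.labels == 1)

    def test_partition_stable_under_frame_permutation(self):
        res = simulate_toy_markov(ToyLandscapeSpec(
            transition=np.array([[0.9, 0.1], [0.1, 0.9]]),
            n_frames=300, jitter=0.3, seed=2))
        m1 = cluster_trajectories([res.trajectory], k_range=[2], seed=0)
        perm = np.random.default_rng(0).permutation(300)
        shuffled = res.trajectory.coords[perm]
        m2 = cluster_trajectories([shuffled], k_range=[2], seed=0)
        # same partition up to label permutation
        back = np.empty_like(m2.labels)
        back[perm] = m2.labels
        agreement = max(np.mean(back == m1.labels),
                        np.mean(back == (3 - m1.labels)))
        assert agreement == 1.0

    def test_zero_jitter_recovers_planted_states(self):
        P = np.array([[0.95, 0.03, 0.02],
                      [0.03, 0.94, 0.03],
                      [0.02, 0.02, 0.96]])
        res = simulate_toy_markov(ToyLandscapeSpec(
            transition=P, n_frames=600, jitter=0.0, seed=3))
        model = cluster_trajectories([res.trajectory], k_range=range(1, 8),
                                     seed=0)
        assert model.k == 3
        hit = any(
            np.array_equal(np.array([perm[s - 1] for s in res.states]),
                           model.labels)
            for perm in itertools.permutations((1, 2, 3)))
        assert hit

    def test_knee_point_simple_curve(self):
        ys = np.array([100.0, 40.0, 12.0, 10.0, 9.0, 8.5])
        ks = np.arange(1, 7)
        assert ks[knee_point(ks, ys)] == 3


class TestCounting:
    def test_lag_one_counts(self):
        net = count_transitions([1, 1, 2, 2], lag=1)
        np.testing.assert_array_equal(net.counts, [[1, 1], [0, 1]])

    def test_no_counting_across_trajectory_boundaries(self):
        net = count_transitions([[1, 1], [2, 2]], lag=1)
        np.testing.assert_array_equal(net.counts, [[1, 0], [0, 1]])

    def test_uniform_random_labels_give_uniform_pi(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(1, 4, size=30000)
        net = count_transitions(labels, lag=1)
        np.testing.assert_allclose(net.pi, 1 / 3, atol=0.02)

    def test_free_energy_from_stationary_weights(self):
        net = network([[8, 2], [2, 8]], kbt=0.5)
        np.testing.assert_allclose(net.free_energies,
                                   -0.5 * np.log([0.5, 0.5]))

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            count_transitions([], lag=1)
        with pytest.raises(ValueError):
            count_transitions([1, 2], lag=0)

    def test_sliding_window_lag(self):
        net = count_transitions([1, 2, 1, 2, 1], lag=2)
        # windows: (1,1),(2,2),(1,1)
        np.testing.assert_array_equal(net.counts, [[2, 0], [0, 1]])


class TestMinCut:
    def test_three_node_chain_hand_enumeration(self):
        # n12 = n21 = 5, n23 = n32 = 1 -> N_total = 12, min cut {1,2}|{3} = 2
        net = network([[0, 5, 0], [5, 0, 1], [0, 1, 0]], kbt=1.0)
        barrier, cut = mincut_barrier(net, [1], [3])
        assert cut == 2.0
        assert barrier == pytest.approx(np.log(6.0))

    def test_disconnected_components_infinite(self):
        net = network([[0, 5, 0, 0], [5, 0, 0, 0],
                       [0, 0, 0, 3], [0, 0, 3, 0]])
        barrier, cut = mincut_barrier(net, [1], [4])
        assert barrier == np.inf and cut == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 10, (6, 6)).astype(float)
        net = network(counts)
        b1, _ = mincut_barrier(net, [1, 2], [5, 6])
        b2, _ = mincut_barrier(net, [5, 6], [1, 2])
        assert b1 == pytest.approx(b2)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        counts = rng.integers(0, 6, (n, n)).astype(float)
        counts += counts.T  # keep everything loosely connected
        np.fill_diagonal(counts, 0)
        net = network(counts)
        A, B = [1], [n]
        _, cut = mincut_barrier(net, A, B)
        assert cut == pytest.approx(brute_force_mincut(net, A, B))

    def test_parallel_capacity_never_raises_barrier(self):
        counts = np.array([[0, 3, 0], [3, 0, 2], [0, 2, 0]], float)
        net = network(counts)
        b0, _ = mincut_barrier(net, [1], [3])
        counts2 = counts.copy()
        counts2[0, 2] = counts2[2, 0] = 4  # add a parallel route
        net2 = network(counts2)
        b1, _ = mincut_barrier(net2, [1], [3])
        assert b1 <= b0

    def test_overlapping_sets_rejected(self):
        net = network([[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            mincut_barrier(net, [1], [1])


class TestTRDG:
    def test_two_minima_single_merge(self):
        net = network([[0, 4], [4, 0]], kbt=1.0)
        tree = build_trdg(net)
        assert tree.n_leaves == 2
        assert tree.merges.shape == (1, 4)
        barrier, _ = mincut_barrier(net, [1], [2])
        assert tree.merges[0, 2] == pytest.approx(barrier)

    def test_hierarchical_merge_order(self):
        # two tight pairs (1,2) and (3,4), weak bridge between them
        counts = np.array([[0, 50, 1, 0],
                           [50, 0, 0, 1],
                           [1, 0, 0, 60],
                           [0, 1, 60, 0]], float)
        net = network(counts, kbt=1.0)
        tree = build_trdg(net)
        heights = tree.merges[:, 2]
        # merges: (3,4) first (largest cut), then (1,2), bridge last
        assert heights[0] < heights[1] < heights[2]
        first = {int(tree.merges[0, 0]), int(tree.merges[0, 1])}
        assert first == {2, 3}  # leaf indices of states 3 and 4
        # separating the pairs cuts both bridge edges: (1+1) + (1+1) = 4
        cuts = pairwise_mincut(net)
        assert cuts[0, 2] == 4.0

    @pytest.mark.parametrize("seed", range(4))
    def test_ultrametric_inequality(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        counts = rng.integers(1, 20, (n, n)).astype(float)
        np.fill_diagonal(counts, 0)
        net = network(counts)
        tree = build_trdg(net)
        for i, j, k in itertools.combinations(range(n), 3):
            hij = tree.merge_height(i, j)
            hik = tree.merge_height(i, k)
            hjk = tree.merge_height(j, k)
            assert max(hij, hik, hjk) <= max(
                sorted([hij, hik, hjk])[1] + 1e-9, max(hij, hik, hjk))
            # the two largest of the three must be equal
            top2 = sorted([hij, hik, hjk])[1:]
            assert top2[0] == pytest.approx(top2[1], abs=1e-9)

    def test_barriers_not_below_leaf_energies(self):
        res = simulate_toy_markov(ToyLandscapeSpec(
            transition=np.array([[0.97, 0.03], [0.05, 0.95]]),
            n_frames=4000, jitter=0.3, seed=6))
        net = count_transitions(res.states, lag=1,
                                temperature=298.0)
        tree = build_trdg(net)
        assert tree.merges[:, 2].min() >= tree.leaf_energies.min()

    def test_annotations_attached(self):
        labels = np.array([1, 1, 2, 2, 2])
        chis = np.array([0.1, 0.2, 0.5, 0.4, 0.1])
        ann = annotate_states(labels, chis, chi_c=0.30)
        assert ann[1]["chi_min"] == pytest.approx(0.1)
        assert ann[1]["fibril_fraction"] == 0.0
        assert ann[2]["chi_max"] == pytest.approx(0.5)
        assert ann[2]["fibril_fraction"] == pytest.approx(2 / 3)


class TestRoughness:
    def test_single_funnel_zero_everywhere(self):
        tree = DisconnectivityTree(
            states=np.array([1, 2]), leaf_energies=np.array([0.0, 1.0]),
            merges=np.array([[0.0, 1.0, 1.0, 2.0]]))
        profile = roughness_profile(tree, delta_f=0.25)
        # the second branch is born exactly where it merges: never 2 alive
        assert np.all(profile.rho == 0.0)

    def test_two_branches_over_one_bin(self):
        tree = DisconnectivityTree(
            states=np.array([1, 2]), leaf_energies=np.array([0.0, 0.0]),
            merges=np.array([[0.0, 1.0, 1.0, 2.0]]))
        delta_f = 1.0
        profile = roughness_profile(tree, delta_f=delta_f)
        assert profile.rho[0] == pytest.approx(1.0 / (2 * delta_f))

    def test_doubling_bin_width_halves_density(self):
        tree = DisconnectivityTree(
            states=np.array([1, 2]), leaf_energies=np.array([0.0, 0.0]),
            merges=np.array([[0.0, 1.0, 2.0, 2.0]]))
        p1 = roughness_profile(tree, delta_f=0.5)
        p2 = roughness_profile(tree, delta_f=1.0)
        assert p1.rho.max() == pytest.approx(2 * p2.rho.max())

    def test_invalid_bin_width_rejected(self):
        tree = DisconnectivityTree(states=np.array([1]),
                                   leaf_energies=np.array([0.0]),
                                   merges=np.empty((0, 4)))
        with pytest.raises(ValueError):
            roughness_profile(tree, delta_f=0.0)


def test_end_to_end_double_well_recovers_two_basins():
    """Two-state toy landscape: TRDG finds 2 basins, barrier matches rates."""
    p12, p21 = 0.02, 0.04
    n_frames = 20000
    P = np.array([[1 - p12, p12], [p21, 1 - p21]])
    res = simulate_toy_markov(ToyLandscapeSpec(
        transition=P, n_frames=n_frames, jitter=0.25, seed=8))
    model = cluster_trajectories([res.trajectory], k_range=range(1, 6),
                                 seed=0)
    assert model.k == 2
    net = count_transitions(model.labels_per_trajectory(), lag=1)
    tree = build_trdg(net)
    assert tree.n_leaves == 2
    # stationary weights from counts vs detailed balance p21/(p12+p21)
    pi_expected = np.array([p21, p12]) / (p12 + p21)
    pi = np.sort(net.pi)[::-1]
    # occupancy SE ~ sqrt(pi1 pi2 * 2/(p12+p21) / n) ~= 0.02; allow 3 SE
    np.testing.assert_allclose(np.sort(pi_expected)[::-1], pi, atol=0.06)
    # cut value ~= expected number of 1<->2 transitions
    _, cut = mincut_barrier(net, [net.states[0]], [net.states[1]])
    expected_cut = 2 * n_frames * pi_expected[0] * p12
    assert cut == pytest.approx(expected_cut, rel=0.2)
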