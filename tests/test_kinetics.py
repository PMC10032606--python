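"""Markov-chain spectra, graph-transformation MFPTs, FPT statistics."""

import numpy as np
import pytest

from nstarkit.fixtures import (ToyLandscapeSpec, make_toy_reference,
                               simulate_toy_markov, toy_template)
from nstarkit.kinetics import (FPTSample, TransitionMatrix,
                               first_passage_from_trajectories,
                               fpt_statistics, implied_timescales,
                               mfpt_graph_transform, mfpt_linear_solve,
                               transition_matrix)
from nstarkit.landscape import TransitionNetwork, count_transitions


def network(counts, kbt=1.0, dt=None):
    counts = np.asarray(counts, dtype=float)
    return TransitionNetwork(states=np.arange(1, counts.shape[0] + 1),
                             counts=counts, lag=1, kbt=kbt, dt_frame_ps=dt)


def random_chain(rng, n):
    T = rng.random((n, n)) ** 2 + 1e-6
    return T / T.sum(axis=1, keepdims=True)


class TestTransitionMatrix:
    def test_row_normalisation(self):
        tm = transition_matrix(network([[9, 1], [1, 9]]))
        np.testing.assert_allclose(tm.T, [[0.9, 0.1], [0.1, 0.9]])

    def test_leading_eigenvalue_is_one(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 20, (5, 5)).astype(float)
        tm = transition_matrix(network(counts))
        assert tm.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.abs(tm.eigenvalues) <= 1.0 + 1e-10)

    def test_detailed_balance_spectrum_is_real(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 30, (6, 6)).astype(float)
        tm = transition_matrix(network(counts))
        assert np.isrealobj(tm.eigenvalues)

    def test_stationary_matches_count_weights(self):
        net = network([[5, 3], [3, 9]])
        tm = transition_matrix(net)
        np.testing.assert_allclose(tm.stationary, net.pi, atol=1e-10)

    def test_dead_state_rejected_by_name(self):
        counts = np.array([[2, 0, 0], [0, 3, 0], [0, 0, 0]], float)
        with pytest.raises(ValueError, match="3"):
            transition_matrix(network(counts))


class TestImpliedTimescales:
    def test_closed_form_two_state(self):
        tm = TransitionMatrix(T=np.array([[0.9, 0.1], [0.1, 0.9]]), lag=1.0)
        assert implied_timescales(tm)[0] == pytest.approx(1 / np.log(1.25))

    def test_closed_form_lambda_half(self):
        ts = implied_timescales(np.array([[0.5, 0.5], [0.5, 0.5]]), lag=1.0)
        # lambda_2 = 0 -> instantaneous decay
        assert ts[0] == 0.0
        tm = TransitionMatrix(T=np.array([[0.75, 0.25], [0.25, 0.75]]),
                              lag=1.0)
        assert implied_timescales(tm)[0] == pytest.approx(1 / np.log(2.0))

    def test_disconnected_chain_flagged_infinite(self):
        T = np.eye(2)
        with pytest.warns(UserWarning, match="disconnected"):
            ts = implied_timescales(T, lag=1.0)
        assert ts[0] == np.inf

    def test_lag_independence_on_markov_data(self):
        # exact Markov trajectories: t_i(tau) flat across lag times
        P = np.array([[0.97, 0.03], [0.06, 0.94]])
        res = simulate_toy_markov(ToyLandscapeSpec(
            transition=P, n_frames=60000, jitter=0.0, seed=1))
        truth = res.ground_truth["implied_timescales"][0]
        estimates = []
        for lag in (1, 2, 5, 10):
            net = count_transitions(res.states, lag=lag)
            tm = transition_matrix(net, lag=lag)
            estimates.append(implied_timescales(tm)[0])
        np.testing.assert_allclose(estimates, truth, rtol=0.15)

    def test_invariant_under_state_relabelling(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 25, (5, 5)).astype(float)
        perm = rng.permutation(5)
        ts1 = implied_timescales(transition_matrix(network(counts)))
        ts2 = implied_timescales(
            transition_matrix(network(counts[np.ix_(perm, perm)])))
        np.testing.assert_allclose(ts1, ts2, rtol=1e-10)


class TestGraphTransformation:
    def test_two_state_geometric_escape(self):
        T = np.array([[0.9, 0.1], [0.0, 1.0]])
        assert mfpt_graph_transform(T, [0], [1]) == pytest.approx(10.0)

    def test_source_equals_target(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        assert mfpt_graph_transform(T, [0], [0]) == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_linear_solve(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 21))
        T = random_chain(rng, n)
        src = [0]
        tgt = list(rng.choice(np.arange(1, n),
                              size=int(rng.integers(1, max(2, n // 3))),
                              replace=False))
        gt = mfpt_graph_transform(T, src, tgt)
        ls = mfpt_linear_solve(T, src, tgt)
        assert gt == pytest.approx(ls, rel=1e-10)

    def test_set_to_set_with_stationary_weights(self):
        rng = np.random.default_rng(5)
        T = random_chain(rng, 8)
        gt = mfpt_graph_transform(T, [0, 1, 2], [7])
        ls = mfpt_linear_solve(T, [0, 1, 2], [7])
        assert gt == pytest.approx(ls, rel=1e-10)

    def test_unreachable_target_is_infinite(self):
        T = np.array([[1.0, 0.0, 0.0],
                      [0.0, 0.5, 0.5],
                      [0.0, 0.5, 0.5]])
        assert mfpt_graph_transform(T, [0], [2]) == np.inf

    def test_physical_units_from_network(self):
        net = network([[9, 1], [1, 9]], dt=660.0)  # 0.66 ns per frame
        tm = transition_matrix(net)
        value = mfpt_graph_transform(tm, [1], [2])
        steps = mfpt_graph_transform(tm.T, [0], [1])
        assert value == pytest.approx(steps * 660.0)


class TestFPTStatistics:
    def test_constant_sample(self):
        sample = FPTSample(times=np.full(10, 5.0),
                           censored=np.zeros(10, bool), unit="us")
        stats = fpt_statistics(sample)
        assert stats.mean == pytest.approx(5.0)
        assert stats.jackknife_se == pytest.approx(0.0, abs=1e-12)

    def test_exponential_sample_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(25.0, size=10000)
        sample = FPTSample(times=x, censored=np.zeros(len(x), bool))
        stats = fpt_statistics(sample)
        assert abs(stats.mean - 25.0) < 3 * stats.jackknife_se
        assert stats.exponential["acceptable"]

    def test_bimodal_mixture_flags_log_gaussian_poor(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.lognormal(0.0, 0.1, 4000),
                            rng.lognormal(5.0, 0.1, 4000)])
        sample = FPTSample(times=x, censored=np.zeros(len(x), bool))
        stats = fpt_statistics(sample)
        assert not stats.log_gaussian["acceptable"]

    def test_unimodal_log_gaussian_accepted(self):
        rng = np.random.default_rng(4)
        x = rng.lognormal(2.0, 0.5, 3000)
        sample = FPTSample(times=x, censored=np.zeros(len(x), bool))
        assert fpt_statistics(sample).log_gaussian["acceptable"]

    def test_censored_excluded_but_reported(self):
        sample = FPTSample(times=np.array([1.0, 2.0, 3.0, 9.0]),
                           censored=np.array([False, False, False, True]))
        stats = fpt_statistics(sample)
        assert stats.mean == pytest.approx(2.0)
        assert stats.censoring_fraction == pytest.approx(0.25)

    def test_too_few_samples_rejected(self):
        sample = FPTSample(times=np.array([1.0]),
                           censored=np.array([False]))
        with pytest.raises(ValueError):
            fpt_statistics(sample)


class TestFirstPassageFromTrajectories:
    def make_trajectory(self, hit_frame, n_frames=12, dt=660.0):
        """Frames: extended (RC) until hit_frame, hairpin-U afterwards."""
        from nstarkit.bd import Trajectory

        ext = toy_template("extended")
        hairpin = toy_template("hairpin-U")
        coords = np.array([hairpin if f >= hit_frame else ext
                           for f in range(n_frames)])
        return Trajectory(coords, dt_save_ps=dt)

    def test_hit_time_arithmetic(self):
        refs = [make_toy_reference("hairpin-U")]
        traj = self.make_trajectory(hit_frame=7, dt=660.0)
        sample = first_passage_from_trajectories(
            [traj], refs, direction="RC->hairpin-U")
        assert sample.times[0] == pytest.approx(7 * 660.0)  # = 4.62 ns
        assert not sample.censored[0]

    def test_start_in_target_excluded_with_warning(self):
        refs = [make_toy_reference("hairpin-U")]
        traj = self.make_trajectory(hit_frame=0)
        with pytest.warns(UserWarning, match="starts inside"):
            sample = first_passage_from_trajectories(
                [traj], refs, direction="RC->hairpin-U")
        assert len(sample.times) == 0
        assert sample.n_excluded_start == 1

    def test_never_hitting_is_censored(self):
        refs = [make_toy_reference("meander-S")]
        traj = self.make_trajectory(hit_frame=10**9)
        sample = first_passage_from_trajectories(
            [traj], refs, direction="RC->meander-S")
        assert sample.censored[0]
        assert sample.censoring_fraction == 1.0

    def test_single_frame_trajectory_rejected(self):
        from nstarkit.bd import Trajectory

        refs = [make_toy_reference("hairpin-U")]
        traj = Trajectory(toy_template("extended")[None], dt_save_ps=1.0)
        with pytest.raises(ValueError, match="shorter"):
            first_passage_from_trajectories([traj], refs)

    def test_two_state_generator_mfpt_recovery(self):
        # hidden chain: state 1 = extended (RC), state 2 = hairpin (N*);
        # empirical MFPT to the hairpin class vs the analytic value
        p = 0.02
        P = np.array([[1 - p, p], [0.2, 0.8]])
        analytic = 1.0 / p  # frames, from the geometric escape
        times = []
        for rep in range(150):
            res = simulate_toy_markov(ToyLandscapeSpec(
                transition=P, n_frames=600, jitter=0.3, seed=1000 + rep,
                start_state=0, dt_frame_ps=1.0,
                templates=np.stack([toy_template("extended"),
                                    toy_template("hairpin-U")])))
            hits = np.nonzero(res.states == 2)[0]
            if len(hits):
                times.append(hits[0])
        sample = FPTSample(times=np.array(times, float) + 1e-12,
                           censored=np.zeros(len(times), bool))
        stats = fpt_statistics(sample)
        # mild censoring bias: tolerate 3 SE around the censored-adjusted mean
        assert abs(stats.mean - analytic) < 3 * stats.jackknife_se + \
            analytic * 0.05

        refs = [make_toy_reference("extended"),
                make_toy_reference("hairpin-U")]
        res = simulate_toy_markov(ToyLandscapeSpec(
            transition=P, n_frames=600, jitter=0.3, seed=77, start_state=0,
            dt_frame_ps=1.0,
            templates=np.stack([toy_template("extended"),
                                toy_template("hairpin-U")])))
        sample2 = first_passage_from_trajectories(
            [res.trajectory], refs, direction="RC->hairpin-U")
        hits = np.nonzero(res.states == 2)[0]
        assert sample2.times[0] == pytest.approx(hits[0] * 1.0)
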