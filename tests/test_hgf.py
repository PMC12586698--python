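"""Filter core: prediction, update, normalisation, full-stream filtering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cathgf import (
    SEQUENCE_A,
    HGFParameters,
    NodeState,
    filter_trials,
    init_network,
    normalized_prediction,
    predict_step,
    update_step,
)
from cathgf.hgf import sigmoid

finite_mu = st.floats(-20, 20, allow_nan=False)
pos_pi = st.floats(1e-6, 1e6, allow_nan=False)


class TestInitNetwork:
    def test_sixteen_nodes_uniform_prediction(self):
        grid = init_network(HGFParameters(omega=-4.0))
        assert grid.shape == (4, 4) and grid.size == 16
        mu_hat = np.array([[n.mu for n in row] for row in grid])
        assert np.allclose(normalized_prediction(mu_hat), 0.25)

    def test_nonpositive_precision_rejected(self):
        with pytest.raises(ValueError, match="pi0"):
            HGFParameters(omega=-4.0, pi0=0.0)


class TestPredictStep:
    def test_zero_omega_unit_volatility(self):
        state = predict_step(NodeState(mu=0.0, pi=1.0), HGFParameters(0.0))
        assert state.pi_hat == pytest.approx(1.0 / (1.0 + 1.0))  # Omega = 1

    def test_closed_form(self):
        state = predict_step(NodeState(mu=0.3, pi=2.0), HGFParameters(-2.0))
        assert state.mu_hat == 0.3
        assert state.pi_hat == pytest.approx(1.0 / (0.5 + math.exp(-2.0)), abs=1e-10)
        assert state.pi_hat == pytest.approx(1.5740, abs=1e-4)

    def test_no_forgetting_limit(self):
        state = predict_step(NodeState(mu=1.0, pi=3.0), HGFParameters(-700.0))
        assert state.pi_hat == pytest.approx(3.0, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(mu=finite_mu, pi=pos_pi, omega=st.floats(-20, 5))
    def test_precision_strictly_shrinks(self, mu, pi, omega):
        state = predict_step(NodeState(mu=mu, pi=pi), HGFParameters(omega))
        assert 0 < state.pi_hat < pi
        assert state.mu_hat == mu


class TestUpdateStep:
    def test_closed_form_and_mirror(self):
        base = NodeState(mu=0.0, pi=1.0, mu_hat=0.0, pi_hat=1.0)
        up = update_step(base, 1)
        assert up.delta == pytest.approx(0.5)
        assert up.pi == pytest.approx(1.25)
        assert up.mu == pytest.approx(0.4)
        down = update_step(base, 0)
        assert down.mu == pytest.approx(-0.4)

    def test_zero_prediction_error_no_update(self):
        # b_hat = 0.5 cannot equal a binary outcome, so drive b_hat -> 1
        state = NodeState(mu=40.0, pi=1.0, mu_hat=40.0, pi_hat=1.0)
        up = update_step(state, 1)
        assert up.mu == pytest.approx(40.0, abs=1e-10)

    @settings(derandomize=True, max_examples=50)
    @given(mu_hat=st.floats(-8, 8), pi_hat=st.floats(1e-3, 1e3),
           observed=st.integers(0, 1))
    def test_update_invariants(self, mu_hat, pi_hat, observed):
        state = update_step(
            NodeState(mu=mu_hat, pi=pi_hat, mu_hat=mu_hat, pi_hat=pi_hat), observed
        )
        assert state.pi > pi_hat  # observation adds precision
        assert abs(state.delta) <= 1
        assert np.sign(state.mu - mu_hat) == np.sign(state.delta)

    def test_shift_decreasing_in_predicted_precision(self):
        lo = update_step(NodeState(mu=0, pi=1, mu_hat=0.0, pi_hat=0.5), 1)
        hi = update_step(NodeState(mu=0, pi=1, mu_hat=0.0, pi_hat=5.0), 1)
        assert abs(lo.mu - lo.mu_hat) > abs(hi.mu - hi.mu_hat)

    def test_requires_prediction(self):
        with pytest.raises(ValueError, match="predict_step"):
            update_step(NodeState(mu=0.0, pi=1.0), 1)


class TestNormalizedPrediction:
    def test_uniform(self):
        assert np.allclose(normalized_prediction(np.zeros((4, 4))), 0.25)

    def test_against_direct_evaluation(self):
        mu_hat = np.zeros((4, 4))
        mu_hat[0] = [0.0, 0.0, 0.0, 50.0]
        p = normalized_prediction(mu_hat)
        s = 1.0 / (1.0 + np.exp(-mu_hat[0]))
        assert np.allclose(p[0], s / s.sum())
        assert p[0, 3] == pytest.approx(1.0 / 2.5, abs=1e-6)  # 0.4

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(finite_mu, min_size=16, max_size=16), st.integers(0, 3),
           st.floats(0.1, 5))
    def test_rows_sum_to_one_and_monotonicity(self, values, j, bump):
        mu_hat = np.array(values).reshape(4, 4)
        p = normalized_prediction(mu_hat)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((p > 0) & (p < 1))
        bumped = mu_hat.copy()
        bumped[0, j] += bump
        q = normalized_prediction(bumped)
        assert q[0, j] > p[0, j]
        others = [k for k in range(4) if k != j]
        assert np.all(q[0, others] < p[0, others])


def straight_line_filter(stimuli, omega, mu0=0.0, pi0=1.0):
    """Independent plain-Python re-implementation of the four formulas."""
    mu = [[mu0] * 4 for _ in range(4)]
    pi = [[pi0] * 4 for _ in range(4)]
    out = []
    for t, s in enumerate(stimuli):
        if t == 0:
            mu_hat = [row[:] for row in mu]
            pi_hat = [row[:] for row in pi]
        else:
            mu_hat = [row[:] for row in mu]
            pi_hat = [
                [1.0 / (1.0 / pi[a][b] + math.exp(omega)) for b in range(4)]
                for a in range(4)
            ]
        pred = []
        for a in range(4):
            sig = [1.0 / (1.0 + math.exp(-m)) for m in mu_hat[a]]
            tot = sum(sig)
            pred.append([x / tot for x in sig])
        mu = [row[:] for row in mu_hat]
        pi = [row[:] for row in pi_hat]
        if t > 0:
            i, j = stimuli[t - 1] - 1, s - 1
            for b in range(4):
                bh = 1.0 / (1.0 + math.exp(-mu_hat[i][b]))
                delta = (1.0 if b == j else 0.0) - bh
                pi[i][b] = pi_hat[i][b] + bh * (1.0 - bh)
                mu[i][b] = mu_hat[i][b] + delta / pi[i][b]
        out.append((mu_hat, pi_hat, pred, [row[:] for row in mu], [row[:] for row in pi]))
    return out


class TestFilterTrials:
    def test_single_transition_hand_trace(self):
        traj = filter_trials([1, 4], HGFParameters(omega=-700.0))
        # pi_hat ~= pi0 = 1, so the observed node moves to 0.4 and its three
        # siblings mirror to -0.4 (all start at mu=0, pi=1)
        assert traj.mu[1, 0, 3] == pytest.approx(0.4, abs=1e-10)
        assert np.allclose(traj.mu[1, 0, :3], -0.4, atol=1e-10)
        assert np.allclose(traj.mu[1, 1:], 0.0)  # inactive rows untouched
        assert traj.delta[1, 0, 3] == pytest.approx(0.5, abs=1e-12)

    def test_matches_straight_line_oracle(self):
        stimuli = list(SEQUENCE_A[:20])
        omega = -3.0
        traj = filter_trials(stimuli, HGFParameters(omega))
        oracle = straight_line_filter(stimuli, omega)
        for t, (mu_hat, pi_hat, pred, mu, pi) in enumerate(oracle):
            assert np.allclose(traj.mu_hat[t], mu_hat, atol=1e-10)
            assert np.allclose(traj.pi_hat[t], pi_hat, atol=1e-10)
            assert np.allclose(traj.predicted[t], pred, atol=1e-10)
            assert np.allclose(traj.mu[t], mu, atol=1e-10)
            assert np.allclose(traj.pi[t], pi, atol=1e-10)

    def test_unseen_transition_probability_shrinks(self, sim_trials):
        # the task never repeats a category, so p(1 -> 1) is repeatedly
        # disconfirmed and its predicted probability approaches 0
        traj = filter_trials(
            sim_trials["stimulus"].to_numpy(),
            HGFParameters(-4.0),
            sessions=sim_trials["session"].to_numpy(),
        )
        p11 = traj.predicted[:, 0, 0]
        assert p11[0] == pytest.approx(0.25)
        assert p11[-1] < 0.05
        assert p11[-100:].mean() < p11[:100].mean()

    def test_alternation_drives_pair_probabilities_up(self):
        stimuli = [1, 2] * 50
        traj = filter_trials(stimuli, HGFParameters(-4.0))
        p21 = traj.predicted[:, 0, 1]  # p(2 | 1)
        p12 = traj.predicted[:, 1, 0]  # p(1 | 2)
        assert np.all(np.diff(p21) >= -1e-12)
        assert np.all(np.diff(p12) >= -1e-12)
        assert p21[-1] > 0.8 and p12[-1] > 0.8

    def test_rows_sum_to_one_every_trial(self, sim_trajectory):
        sums = sim_trajectory.predicted.sum(axis=2)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_prediction_shrinks_precision_every_trial(self, sim_trajectory):
        assert np.all(sim_trajectory.pi_hat[1:] < sim_trajectory.pi[:-1])

    def test_volatility_monotonicity(self, sim_trials):
        stim = sim_trials["stimulus"].to_numpy()[:400]
        lo = filter_trials(stim, HGFParameters(-6.0))
        hi = filter_trials(stim, HGFParameters(-2.0))
        assert np.all(hi.pi_hat[1:] < lo.pi_hat[1:])
        shift_hi = np.abs(hi.mu - hi.mu_hat).sum(axis=(1, 2))
        shift_lo = np.abs(lo.mu - lo.mu_hat).sum(axis=(1, 2))
        assert shift_hi[1:].mean() > shift_lo[1:].mean()

    def test_forgetting_drives_precision_to_zero(self):
        # with no observations, repeated predictions follow
        # pi_n = 1 / (1/pi0 + n * exp(omega)) -> 0
        omega = -2.0
        state = NodeState(mu=0.0, pi=1.0)
        params = HGFParameters(omega)
        for n in range(1, 50):
            state = predict_step(state, params)
            expected = 1.0 / (1.0 + n * math.exp(omega))
            assert state.pi_hat == pytest.approx(expected, rel=1e-12)
            state = NodeState(mu=state.mu_hat, pi=state.pi_hat)
        assert state.pi < 0.15

    def test_session_boundary_scores_no_transition(self, sim_trajectory):
        t = 960  # first trial of the post session
        assert sim_trajectory.observed_from[t] == -1
        assert np.all(np.isnan(sim_trajectory.delta[t]))
        # but time still passes: precision shrinks across the break
        assert np.all(sim_trajectory.pi_hat[t] < sim_trajectory.pi[t - 1])

    def test_invalid_category_raises(self):
        with pytest.raises(ValueError, match="categor"):
            filter_trials([1, 5, 2], HGFParameters(-4.0))

    def test_long_format_export(self, sim_trajectory):
        frame = sim_trajectory.to_frame()
        assert len(frame) == sim_trajectory.n_trials * 16
        assert list(frame.columns) == [
            "trial", "from", "to", "mu", "pi", "mu_hat", "pi_hat", "delta",
        ]
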