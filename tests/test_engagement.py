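"""Engagement drivers, gamification, social weights, and the RNN."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apeo.engagement import (
    EngagementFactors,
    GamificationParams,
    RNNParams,
    challenge_balance,
    compute_reward,
    decay_engagement,
    engagement_components,
    engagement_value,
    influence_weights,
    init_rnn_params,
    load_rnn_params,
    rnn_forward,
    rnn_gradients,
    rnn_loss,
    rnn_train,
    save_rnn_params,
    update_target,
)
from apeo.errors import DomainError, ShapeError


class TestComponents:
    def test_intrinsic_motivation_ratio(self):
        f = engagement_components(0.8, 0.4, 0.3, 0.6, [0.7], [1.0])
        assert f.intrinsic_M == pytest.approx(2.0)
        assert f.competency_C == pytest.approx(0.5)
        assert f.social_S == pytest.approx(0.7)

    def test_zero_denominators_rejected(self):
        with pytest.raises(DomainError):
            engagement_components(0.8, 0.0, 0.3, 0.6, [], [])
        with pytest.raises(DomainError):
            engagement_components(0.8, 0.4, 0.3, 0.0, [], [])

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(DomainError):
            engagement_components(0.8, 0.4, 0.3, 0.6, [0.5, 0.5], [0.4, 0.4])


class TestInfluenceWeights:
    def test_equal_dot_products_split_evenly(self):
        w = influence_weights(np.zeros(2), np.array([[1.0, 0], [0, 1.0]]))
        assert w == pytest.approx([0.5, 0.5])

    def test_hand_computed_softmax(self):
        # dot products (ln 2, 0) -> (2/3, 1/3)
        theta = np.array([1.0])
        phis = np.array([[np.log(2.0)], [0.0]])
        assert influence_weights(theta, phis) == pytest.approx([2 / 3, 1 / 3])

    def test_no_peers_rejected(self):
        with pytest.raises(DomainError):
            influence_weights(np.array([1.0]), np.empty((0, 1)))

    @given(st.integers(1, 6), st.integers(0, 1000))
    @settings(max_examples=40, deadline=None)
    def test_positive_unit_sum_shift_invariant(self, n_peers, seed):
        rng = np.random.default_rng(seed)
        theta = rng.normal(size=3)
        phis = rng.normal(size=(n_peers, 3))
        w = influence_weights(theta, phis)
        assert np.all(w > 0)
        assert abs(w.sum() - 1.0) < 1e-12
        # shifting all logits by a constant leaves the weights unchanged:
        # adding c*theta/(theta.theta) to each phi shifts every dot by c
        shift = 5.0 * theta / (theta @ theta + 1e-12)
        w2 = influence_weights(theta, phis + shift)
        assert w2 == pytest.approx(w, rel=1e-9)

    def test_overflow_safe(self):
        theta = np.array([1000.0])
        phis = np.array([[1.0], [2.0]])
        w = influence_weights(theta, phis)
        assert np.isfinite(w).all() and abs(w.sum() - 1.0) < 1e-12


class TestEngagementValue:
    def test_neutral_readout_is_half(self):
        f = EngagementFactors(0.0, 0.0, 0.0)
        assert engagement_value(
            f, lambda M, S, C: 1 / (1 + np.exp(-(0.0)))) == 0.5

    def test_monotone_in_intrinsic_motivation(self):
        vals = [engagement_value(EngagementFactors(m, 0.0, 0.0))
                for m in (0.0, 0.5, 1.0, 2.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_clamped_to_unit_interval(self, rng):
        for _ in range(50):
            f = EngagementFactors(
                intrinsic_M=float(rng.uniform(0, 10)),
                social_S=float(rng.normal(0, 5)),
                competency_C=float(rng.uniform(0, 10)),
                noise_eps=float(rng.normal(0, 2)),
            )
            assert 0.0 <= engagement_value(f) <= 1.0


class TestGamification:
    def test_reward_with_bonus(self):
        p = GamificationParams(beta1=1, beta2=1, gamma_bonus=1,
                               T_threshold=0.6)
        R, B = compute_reward(0.8, 0.5, p)
        assert B == pytest.approx(0.2)
        assert R == pytest.approx(1.5)

    def test_no_bonus_below_threshold(self):
        p = GamificationParams(T_threshold=0.6)
        _, B = compute_reward(0.5, 0.9, p)
        assert B == 0.0

    def test_zero_weights_zero_reward(self):
        p = GamificationParams(beta1=0, beta2=0, gamma_bonus=0)
        R, _ = compute_reward(0.9, 0.9, p)
        assert R == 0.0

    def test_challenge_balance(self):
        assert challenge_balance([1.0], [1.0], R=0.0, delta=0.5) == 0.0
        assert challenge_balance([1.0], [0.0], R=1.0, delta=0.5) == \
            pytest.approx(0.5)
        assert challenge_balance([2.0], [1.0], R=7.0, delta=0.0) == 1.0

    def test_update_target(self):
        assert update_target(0.0, 1.0, 0.1) == pytest.approx(0.1)
        assert update_target(0.3, 0.9, 1.0) == pytest.approx(0.9)
        assert update_target(0.4, 0.4, 0.5) == pytest.approx(0.4)
        with pytest.raises(DomainError):
            update_target(0.0, 1.0, 1.5)


class TestDecay:
    def test_three_steps_toward_unit_reward(self):
        e = 0.0
        seen = []
        for _ in range(3):
            e = decay_engagement(e, 1.0, 0.5)
            seen.append(e)
        assert seen == pytest.approx([0.5, 0.75, 0.875])

    def test_no_decay_at_alpha_one(self):
        assert decay_engagement(0.42, 1.0, 1.0) == 0.42

    def test_reward_level_is_fixed_point(self):
        assert decay_engagement(0.7, 0.7, 0.3) == pytest.approx(0.7)

    def test_matches_geometric_closed_form_50_steps(self):
        alpha, R, e0 = 0.9, 0.6, 0.1
        e = e0
        for t in range(1, 51):
            e = decay_engagement(e, R, alpha)
            closed = R + alpha**t * (e0 - R)
            assert abs(e - closed) < 1e-12

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            decay_engagement(0.5, 1.0, 1.2)


class TestRNNForward:
    def test_zero_net_predicts_half(self):
        p = RNNParams(W_h=np.zeros((3, 2)), U_h=np.zeros((3, 3)),
                      b_h=np.zeros(3), W_e=np.zeros(3), b_e=0.0)
        preds = rnn_forward(np.zeros((5, 2)), p)
        assert preds == pytest.approx([0.5] * 5)

    def test_outputs_strictly_inside_unit_interval(self, rng):
        p = init_rnn_params(input_dim=3, hidden_dim=4, seed=0, scale=3.0)
        preds = rnn_forward(rng.normal(size=(20, 3)), p)
        assert np.all((preds > 0) & (preds < 1))

    def test_no_recurrence_forgets_initial_hidden(self, rng):
        p = init_rnn_params(input_dim=2, hidden_dim=3, seed=1)
        p = RNNParams(W_h=p.W_h, U_h=np.zeros((3, 3)), b_h=p.b_h,
                      W_e=p.W_e, b_e=p.b_e)
        x = rng.normal(size=(4, 2))
        a = rnn_forward(x, p, h0=np.zeros(3))
        b = rnn_forward(x, p, h0=np.ones(3))
        assert a == pytest.approx(b)

    def test_shape_mismatch_rejected(self):
        p = init_rnn_params(input_dim=2, seed=0)
        with pytest.raises(ShapeError):
            rnn_forward(np.zeros((4, 3)), p)


class TestRNNTraining:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        p = init_rnn_params(input_dim=2, hidden_dim=3, seed=7)
        dataset = [(rng.normal(size=(5, 2)), rng.uniform(0.2, 0.8, size=5))
                   for _ in range(3)]
        g = rnn_gradients(dataset, p).to_vector()
        v0 = p.to_vector()
        h = 1e-6
        fd = np.empty_like(v0)
        for k in range(v0.size):
            vp, vm = v0.copy(), v0.copy()
            vp[k] += h
            vm[k] -= h
            fd[k] = (rnn_loss(dataset, RNNParams.from_vector(vp, 3, 2))
                     - rnn_loss(dataset, RNNParams.from_vector(vm, 3, 2))) / (2 * h)
        denom = np.maximum(np.abs(fd), 1e-8)
        assert np.max(np.abs(g - fd) / denom) < 1e-5

    def test_loss_decreases_on_constant_target(self, rng):
        dataset = [(rng.normal(size=(6, 2)), np.full(6, 0.8))
                   for _ in range(4)]
        _, trace = rnn_train(dataset, lr=2.0, epochs=50, seed=0)
        assert trace[-1] < trace[0]

    def test_training_is_deterministic(self, rng):
        dataset = [(rng.normal(size=(5, 2)), np.full(5, 0.6))]
        _, t1 = rnn_train(dataset, lr=2.0, epochs=20, seed=3)
        _, t2 = rnn_train(dataset, lr=2.0, epochs=20, seed=3)
        assert t1 == t2

    def test_empty_dataset_rejected(self):
        with pytest.raises(DomainError):
            rnn_train([], epochs=1)

    def test_recovers_known_generator_within_noise_floor(self):
        """Trained on sequences from a known small RNN plus observation
        noise, held-out squared error stays within 2x the noise floor."""
        gen = init_rnn_params(input_dim=2, hidden_dim=3, seed=100, scale=0.8)
        rng = np.random.default_rng(200)
        noise_sd = 0.02
        T = 8

        def make(n):
            out = []
            for _ in range(n):
                x = rng.normal(size=(T, 2))
                e = rnn_forward(x, gen)
                e_obs = np.clip(e + rng.normal(0, noise_sd, size=T), 0.01,
                                0.99)
                out.append((x, e_obs))
            return out

        train, test = make(200), make(50)
        fitted, trace = rnn_train(train, lr=10.0, epochs=2000, seed=0)
        assert trace[-1] < trace[0]
        heldout = rnn_loss(test, fitted) / (50 * T)
        noise_floor = noise_sd**2
        assert heldout <= 2.0 * noise_floor


def test_rnn_params_json_round_trip(tmp_path):
    p = init_rnn_params(input_dim=2, hidden_dim=3, seed=5)
    path = tmp_path / "rnn.json"
    save_rnn_params(p, path)
    q = load_rnn_params(path)
    assert np.array_equal(p.W_h, q.W_h)
    assert np.array_equal(p.U_h, q.U_h)
    assert p.b_e == q.b_e
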