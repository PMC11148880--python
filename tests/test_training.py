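"""Q-learning machinery: schedule, tabular oracle, losses, replay, training."""

import numpy as np
import pytest

from rtautoplan.agent import INCREASE, N_TPPS, PlannerPolicy
from rtautoplan.nn import Adam, DenseNet
from rtautoplan.training import (
    ReplayBuffer,
    TrainingHyperparams,
    Transition,
    action_net_loss,
    epsilon_schedule,
    parameter_net_loss,
    q_update_tabular,
    train,
)


class TestEpsilonSchedule:
    @pytest.mark.parametrize("epi,expected", [(1, 0.99), (3, 0.33), (100, 0.1), (10_000, 0.1)])
    def test_values(self, epi, expected):
        assert epsilon_schedule(epi) == pytest.approx(expected)

    def test_non_increasing(self):
        eps = [epsilon_schedule(i) for i in range(1, 200)]
        assert all(a >= b for a, b in zip(eps, eps[1:]))

    def test_invalid_index_raises(self):
        with pytest.raises(ValueError):
            epsilon_schedule(0)


class TestTabularQ:
    def test_single_update_hand_arithmetic(self):
        Q = np.zeros((2, 2))
        out = q_update_tabular(Q, 0, 1, r=1.0, s_next=1, alpha=0.5, gamma=0.9)
        assert out[0, 1] == pytest.approx(0.5)
        assert Q[0, 1] == 0.0  # input untouched

    def test_zero_learning_rate_is_noop(self):
        Q = np.random.default_rng(0).random((3, 2))
        out = q_update_tabular(Q, 1, 0, r=5.0, s_next=2, alpha=0.0, gamma=0.9)
        np.testing.assert_array_equal(out, Q)

    def test_bellman_fixed_point_unchanged(self):
        # Q already satisfying Q(s,a) = r + gamma * max Q(s') stays put
        gamma = 0.9
        Q = np.array([[1.0, 2.0], [3.0, 0.5]])
        r = Q[0, 1] - gamma * Q[1].max()
        out = q_update_tabular(Q, 0, 1, r=r, s_next=1, alpha=0.7, gamma=gamma)
        np.testing.assert_allclose(out, Q)

    def test_converges_to_value_iteration_on_5_state_mdp(self):
        # deterministic cyclic MDP: a=0 advances one state, a=1 two states
        n_s, n_a, gamma = 5, 2, 0.9
        R = np.array([[1.0, 0.0], [0.0, 2.0], [0.5, 0.5], [2.0, 0.0], [0.0, 1.0]])
        nxt = np.array([[(s + 1) % n_s, (s + 2) % n_s] for s in range(n_s)])
        # value-iteration oracle
        Q_star = np.zeros((n_s, n_a))
        for _ in range(2000):
            Q_star = R + gamma * Q_star.max(axis=1)[nxt]
        # repeated tabular updates with decaying step size
        Q = np.zeros((n_s, n_a))
        visits = np.zeros((n_s, n_a))
        for _ in range(3000):
            for s in range(n_s):
                for a in range(n_a):
                    visits[s, a] += 1
                    alpha = max(0.05, 1.0 / visits[s, a])
                    Q = q_update_tabular(Q, s, a, R[s, a], nxt[s, a], alpha, gamma)
        assert np.max(np.abs(Q - Q_star)) < 1e-3


class TestReplayBuffer:
    @staticmethod
    def _t(i):
        return Transition(np.full(3, float(i)), i % N_TPPS, i % 2, float(i), np.full(3, float(i)))

    def test_seeded_sampling_reproducible(self):
        a = ReplayBuffer(100, seed=4)
        b = ReplayBuffer(100, seed=4)
        for i in range(50):
            a.add(self._t(i))
            b.add(self._t(i))
        sa = [t.r for t in a.sample(20)]
        sb = [t.r for t in b.sample(20)]
        assert sa == sb

    def test_capacity_bound_fifo(self):
        buf = ReplayBuffer(10, seed=0)
        for i in range(25):
            buf.add(self._t(i))
        assert len(buf) == 10
        rewards = {t.r for t in buf._store}
        assert rewards == set(float(i) for i in range(15, 25))

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            ReplayBuffer(4, seed=0).sample(1)

    def test_non_finite_transition_rejected(self):
        with pytest.raises(ValueError):
            Transition(np.array([np.inf]), 0, 0, 0.0, np.array([1.0]))


def constant_net(n_in, n_out, value):
    net = DenseNet((n_in, 4, n_out), seed=0)
    for W in net.weights:
        W[:] = 0.0
    net.biases[-1][:] = value
    return net


def _policy(n_metrics, pnet, anet):
    mapping = [np.array([k % n_metrics]) for k in range(N_TPPS)]
    return PlannerPolicy(pnet, anet, mapping, np.ones(n_metrics))


class TestLosses:
    n = 6

    def _batch(self, r=3.0, size=4):
        s = np.full(self.n, 0.5)
        return [Transition(s, i % N_TPPS, i % 2, r, s) for i in range(size)]

    def test_action_loss_scalar_case(self):
        # prediction 1 vs target r + gamma*max S = 3 + 0 -> (1-3)^2 = 4
        anet = constant_net(2 * self.n, 2, 1.0)
        snet = constant_net(self.n, N_TPPS, 0.0)
        pol = _policy(self.n, snet, anet)
        loss = action_net_loss(self._batch(r=3.0), anet, snet, gamma=0.9, policy=pol)
        assert loss == pytest.approx(4.0)

    def test_action_loss_zero_when_prediction_matches(self):
        anet = constant_net(2 * self.n, 2, 3.0)
        snet = constant_net(self.n, N_TPPS, 0.0)
        pol = _policy(self.n, snet, anet)
        assert action_net_loss(self._batch(r=3.0), anet, snet, 0.0, pol) == pytest.approx(0.0)

    def test_action_loss_permutation_invariant(self):
        anet = constant_net(2 * self.n, 2, 1.0)
        snet = constant_net(self.n, N_TPPS, 0.5)
        pol = _policy(self.n, snet, anet)
        batch = [Transition(np.random.default_rng(i).random(self.n), i % N_TPPS, i % 2,
                            float(i), np.random.default_rng(i + 9).random(self.n))
                 for i in range(6)]
        l1 = action_net_loss(batch, anet, snet, 0.9, pol)
        l2 = action_net_loss(batch[::-1], anet, snet, 0.9, pol)
        assert l1 == pytest.approx(l2)

    def test_parameter_loss_scalar_case(self):
        # S = 2 everywhere, max_a A = 5 -> (2-5)^2 = 9
        snet = constant_net(self.n, N_TPPS, 2.0)
        anet = constant_net(2 * self.n, 2, 5.0)
        pol = _policy(self.n, snet, anet)
        assert parameter_net_loss(self._batch(), snet, anet, pol) == pytest.approx(9.0)

    def test_parameter_loss_zero_at_match_and_nonnegative(self):
        snet = constant_net(self.n, N_TPPS, 5.0)
        anet = constant_net(2 * self.n, 2, 5.0)
        pol = _policy(self.n, snet, anet)
        assert parameter_net_loss(self._batch(), snet, anet, pol) == pytest.approx(0.0)
        snet2 = constant_net(self.n, N_TPPS, -1.0)
        assert parameter_net_loss(self._batch(), snet2, anet, pol) >= 0.0

    def test_empty_batch_rejected(self):
        anet = constant_net(2 * self.n, 2, 0.0)
        snet = constant_net(self.n, N_TPPS, 0.0)
        pol = _policy(self.n, snet, anet)
        with pytest.raises(ValueError):
            action_net_loss([], anet, snet, 0.9, pol)


class OneGoodTppEnv:
    """Toy planning environment: exactly one priority slot improves the plan
    score, every other adjustment worsens it.  The optimal policy is known by
    enumeration, so trained behavior can be checked exactly."""

    n_metrics = 21

    def __init__(self, good_p: int, seed: int = 0):
        self.good_p = good_p
        self.tpp_metric_indices = [np.array([k]) for k in range(N_TPPS)]
        self.score_max_points = np.ones(self.n_metrics)
        self._rng = np.random.default_rng(seed)
        self._s = np.full(self.n_metrics, 0.5)

    def reset(self):
        self._s = np.full(self.n_metrics, 0.5) + self._rng.uniform(-0.02, 0.02, self.n_metrics)
        return self._s.copy()

    def step(self, p, a):
        r = 1.0 if p == self.good_p else -1.0
        return self._s.copy(), r, False


class TestTrain:
    hyper_small = dict(steps_per_episode=5, hidden=(32, 16), batch_size=16)

    def test_zero_episodes_is_noop(self):
        env = OneGoodTppEnv(good_p=2)
        _, _, history = train(env, TrainingHyperparams(episodes=0, **self.hyper_small))
        assert history.empty

    def test_history_bookkeeping_and_epsilon_trace(self):
        env = OneGoodTppEnv(good_p=1)
        hyper = TrainingHyperparams(episodes=12, seed=5, **self.hyper_small)
        _, _, history = train(env, hyper)
        assert len(history) == 12 * 5
        for epi, grp in history.groupby("episode"):
            assert np.allclose(grp.epsilon, epsilon_schedule(int(epi)))

    def test_reproducible_given_seed(self):
        out = []
        for _ in range(2):
            env = OneGoodTppEnv(good_p=3, seed=9)
            pnet, anet, hist = train(env, TrainingHyperparams(episodes=15, seed=3,
                                                              **self.hyper_small))
            out.append((pnet, anet, hist))
        (p1, a1, h1), (p2, a2, h2) = out
        assert h1.equals(h2)
        for w1, w2 in zip(p1.parameters() + a1.parameters(),
                          p2.parameters() + a2.parameters()):
            np.testing.assert_array_equal(w1, w2)

    @pytest.mark.parametrize("good_p", [0, 4])
    def test_learns_the_single_good_tpp(self, good_p):
        # across 10 seeds the greedy policy must pick the uniquely rewarding
        # slot in at least 90% of perturbed evaluation states
        hits = total = 0
        for seed in range(10):
            env = OneGoodTppEnv(good_p=good_p, seed=seed)
            pnet, anet, _ = train(env, TrainingHyperparams(
                episodes=150, seed=seed, learning_rate=3e-3, **self.hyper_small))
            policy = PlannerPolicy(pnet, anet, env.tpp_metric_indices, env.score_max_points)
            rng = np.random.default_rng(1000 + seed)
            for _ in range(20):
                s = np.full(21, 0.5) + rng.uniform(-0.02, 0.02, 21)
                p, _ = policy.act(s)
                hits += p == good_p
                total += 1
        assert hits / total >= 0.9


class TestAdamAndDenseNet:
    def test_gradient_matches_finite_differences(self):
        net = DenseNet((4, 6, 3), seed=2)
        X = np.random.default_rng(0).random((5, 4))
        cols = np.array([0, 1, 2, 0, 1])
        tgt = np.random.default_rng(1).random(5)
        loss, grads = net.loss_mse_selected(X, cols, tgt)
        eps = 1e-6
        for p_idx, param in enumerate(net.parameters()):
            it = np.nditer(param, flags=["multi_index"])
            for _ in range(min(param.size, 3)):  # spot-check a few entries
                idx = it.multi_index
                orig = param[idx]
                param[idx] = orig + eps
                lp, _ = net.loss_mse_selected(X, cols, tgt)
                param[idx] = orig - eps
                lm, _ = net.loss_mse_selected(X, cols, tgt)
                param[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert grads[p_idx][idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)
                next(it, None)

    def test_adam_reduces_regression_loss(self):
        net = DenseNet((3, 8, 1), seed=0)
        opt = Adam(net.parameters(), lr=1e-2)
        rng = np.random.default_rng(0)
        X = rng.random((64, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        first = None
        for _ in range(200):
            loss, grads = net.loss_mse_selected(X, np.zeros(64, dtype=int), y)
            if first is None:
                first = loss
            opt.step(grads)
        assert loss < 0.05 * first
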