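"""Q-learning of the two-level planning policy with experience replay.

The two networks are trained alternately, each held fixed while the other
updates.  The action network does standard temporal-difference regression
toward r + gamma * max_p S(s', p); the parameter network is then fit, as a
supervised problem, to max_a A(s, p, a) at the stored states.  Exploration
is epsilon-greedy with epsilon = max(0.1, 0.99 / episode), and transitions
(s, p, a, r, s') are replayed uniformly from a bounded pool.

Everything is driven by explicit numpy generators, so a training run is a
pure function of (environment, hyperparameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .agent import (
    DEFAULT_HIDDEN,
    N_TPPS,
    PlannerPolicy,
    action_net_input,
    select_action,
    select_tpp,
)
from .nn import Adam, DenseNet

__all__ = [
    "Transition",
    "ReplayBuffer",
    "TrainingHyperparams",
    "epsilon_schedule",
    "q_update_tabular",
    "action_net_loss",
    "parameter_net_loss",
    "train",
]


def epsilon_schedule(episode_index: int) -> float:
    """Exploration probability: max(0.1, 0.99 / EPI), EPI the episode index."""
    if episode_index < 1:
        raise ValueError(f"episode index must be >= 1, got {episode_index}")
    return max(0.1, 0.99 / episode_index)


def q_update_tabular(
    Q: np.ndarray, s: int, a: int, r: float, s_next: int, alpha: float, gamma: float
) -> np.ndarray:
    """One tabular action-value update:
    Q(s,a) <- Q(s,a) + alpha * [r + gamma * max_a' Q(s',a') - Q(s,a)].

    Reference oracle for the network targets; returns a new table.
    """
    Q = np.asarray(Q, dtype=float).copy()
    Q[s, a] += alpha * (r + gamma * Q[s_next].max() - Q[s, a])
    return Q


@dataclass(frozen=True)
class Transition:
    """(state, slot, direction, reward, next state); states are raw scores."""

    s: np.ndarray
    p: int
    a: int
    r: float
    s_next: np.ndarray

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.s)) and np.all(np.isfinite(self.s_next))
                and np.isfinite(self.r)):
            raise ValueError("transition contains non-finite entries")


class ReplayBuffer:
    """Bounded FIFO pool with seeded uniform sampling."""

    def __init__(self, capacity: int, seed: int = 0):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = int(capacity)
        self._store: list[Transition] = []
        self._cursor = 0
        self._rng = np.random.default_rng(seed)

    def add(self, t: Transition) -> None:
        if len(self._store) < self.capacity:
            self._store.append(t)
        else:
            self._store[self._cursor] = t
            self._cursor = (self._cursor + 1) % self.capacity

    def sample(self, n: int) -> list[Transition]:
        if not self._store:
            raise ValueError("cannot sample from an empty buffer")
        idx = self._rng.integers(0, len(self._store), size=n)
        return [self._store[i] for i in idx]

    def __len__(self) -> int:
        return len(self._store)


@dataclass
class TrainingHyperparams:
    episodes: int = 300
    steps_per_episode: int = 10
    gamma: float = 0.9
    learning_rate: float = 1e-3
    batch_size: int = 32
    buffer_capacity: int = 10_000
    #: action-net updates per parameter-net update (the alternation schedule)
    action_updates_per_param_update: int = 5
    hidden: tuple[int, ...] = DEFAULT_HIDDEN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.episodes < 0 or self.steps_per_episode < 1:
            raise ValueError("invalid episode counts")


def _batch_arrays(batch: Sequence[Transition], policy: PlannerPolicy):
    s = np.stack([policy.normalize(t.s) for t in batch])
    s_next = np.stack([policy.normalize(t.s_next) for t in batch])
    p = np.array([t.p for t in batch], dtype=int)
    a = np.array([t.a for t in batch], dtype=int)
    r = np.array([t.r for t in batch], dtype=float)
    xa = np.stack([action_net_input(sn, pi, policy.mapping) for sn, pi in zip(s, p)])
    return s, s_next, p, a, r, xa


def _action_targets(batch, policy: PlannerPolicy, gamma: float):
    s, s_next, p, a, r, xa = _batch_arrays(batch, policy)
    q_next = policy.parameter_net.forward(s_next)
    return xa, a, r + gamma * q_next.max(axis=1)


def action_net_loss(batch: Sequence[Transition], action_net: DenseNet,
                    parameter_net: DenseNet, gamma: float,
                    policy: PlannerPolicy) -> float:
    """Mean squared TD error of the action net against r + gamma max_p S(s',p)."""
    if not batch:
        raise ValueError("batch must be nonempty")
    pol = PlannerPolicy(parameter_net, action_net, policy.mapping, policy.max_points)
    xa, a, target = _action_targets(batch, pol, gamma)
    pred = action_net.forward(xa)[np.arange(len(batch)), a]
    return float(np.mean((pred - target) ** 2))


def parameter_net_loss(batch: Sequence[Transition], parameter_net: DenseNet,
                       action_net: DenseNet, policy: PlannerPolicy) -> float:
    """Mean squared error of S(s,p) against max_a A(s,p,a) on the stored pairs."""
    if not batch:
        raise ValueError("batch must be nonempty")
    pol = PlannerPolicy(parameter_net, action_net, policy.mapping, policy.max_points)
    s, _, p, _, _, xa = _batch_arrays(batch, pol)
    target = action_net.forward(xa).max(axis=1)
    pred = parameter_net.forward(s)[np.arange(len(batch)), p]
    return float(np.mean((pred - target) ** 2))


def train(env, hyper: TrainingHyperparams, policy: PlannerPolicy | None = None):
    """Run epsilon-greedy episodes and alternating network updates.

    ``env`` must expose ``reset() -> s`` and ``step(p, a) -> (s', r, done)``
    plus ``tpp_metric_indices`` and ``score_max_points`` describing its state.
    Returns ``(parameter_net, action_net, history)`` where ``history`` is a
    per-step DataFrame (episode, step, epsilon, p, a, r, psi, losses).
    """
    rng = np.random.default_rng(hyper.seed)
    if policy is None:
        n_metrics = len(np.asarray(env.score_max_points))
        policy = PlannerPolicy(
            parameter_net=DenseNet((n_metrics, *hyper.hidden, N_TPPS),
                                   seed=int(rng.integers(2**31)), leaky_slope=0.1),
            action_net=DenseNet((2 * n_metrics, *hyper.hidden, 2),
                                seed=int(rng.integers(2**31)), leaky_slope=0.1),
            mapping=[np.asarray(m, dtype=int) for m in env.tpp_metric_indices],
            max_points=np.asarray(env.score_max_points, dtype=float),
        )
    buffer = ReplayBuffer(hyper.buffer_capacity, seed=int(rng.integers(2**31)))
    opt_a = Adam(policy.action_net.parameters(), lr=hyper.learning_rate)
    opt_s = Adam(policy.parameter_net.parameters(), lr=hyper.learning_rate)

    rows = []
    n_action_updates = 0
    for epi in range(1, hyper.episodes + 1):
        eps = epsilon_schedule(epi)
        s = np.asarray(env.reset(), dtype=float)
        for step in range(1, hyper.steps_per_episode + 1):
            if rng.random() < eps:
                p = int(rng.integers(N_TPPS))
                a = int(rng.integers(2))
            else:
                p, a = policy.act(s)
            s_next, r, done = env.step(p, a)[:3]
            s_next = np.asarray(s_next, dtype=float)
            buffer.add(Transition(s, p, a, float(r), s_next))

            loss_a = loss_s = np.nan
            if len(buffer) >= hyper.batch_size:
                batch = buffer.sample(hyper.batch_size)
                xa, acts, targets = _action_targets(batch, policy, hyper.gamma)
                loss_a, grads = policy.action_net.loss_mse_selected(xa, acts, targets)
                opt_a.step(grads)
                n_action_updates += 1
                if n_action_updates % hyper.action_updates_per_param_update == 0:
                    sb, _, pb, _, _, xab = _batch_arrays(batch, policy)
                    starget = policy.action_net.forward(xab).max(axis=1)
                    loss_s, grads_s = policy.parameter_net.loss_mse_selected(sb, pb, starget)
                    opt_s.step(grads_s)

            rows.append(
                dict(episode=epi, step=step, epsilon=eps, p=p, a=a, r=float(r),
                     psi=float(np.sum(s_next)), action_loss=loss_a, param_loss=loss_s)
            )
            s = s_next
            if done:
                break

    history = pd.DataFrame(
        rows, columns=["episode", "step", "epsilon", "p", "a", "r", "psi",
                       "action_loss", "param_loss"]
    )
    return policy.parameter_net, policy.action_net, history
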