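"""The hierarchical planning agent.

Decision-making is split the way human planners work: a parameter network
looks at the 21 per-metric plan-quality scores and predicts, for each of the
8 adjustable priority slots, the achievable improvement from adjusting it;
an action network then decides the direction (increase or decrease) for the
chosen slot.  The action network sees the original scores concatenated with
a *structure-coded* copy in which only the chosen slot's metrics are kept
(21 + 21 = 42 inputs).  Both are three-hidden-layer MLPs with Leaky ReLU
slope 0.1.

The adjustment magnitude is rule-based, not learned: 6 priority points after
a >20% relative score improvement in the previous adjustment, else 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import DenseNet
from .objectives import PriorityVector
from .scoring import ScoringConfig

__all__ = [
    "INCREASE",
    "DECREASE",
    "N_TPPS",
    "STEP_LARGE",
    "STEP_SMALL",
    "make_parameter_net",
    "make_action_net",
    "structure_coded_vector",
    "select_tpp",
    "select_action",
    "adaptive_step_size",
    "apply_adjustment",
    "PlannerPolicy",
]

INCREASE = 0
DECREASE = 1
N_TPPS = 8
STEP_LARGE = 6.0
STEP_SMALL = 3.0
#: relative score-improvement threshold switching between the two step sizes
STEP_CRITERION = 0.20

DEFAULT_HIDDEN = (128, 64, 32)


def make_parameter_net(seed: int = 0, hidden: tuple[int, ...] = DEFAULT_HIDDEN,
                       n_metrics: int = 21) -> DenseNet:
    """Value network over the 8 adjustable priority slots."""
    return DenseNet((n_metrics, *hidden, N_TPPS), seed=seed, leaky_slope=0.1)


def make_action_net(seed: int = 0, hidden: tuple[int, ...] = DEFAULT_HIDDEN,
                    n_metrics: int = 21) -> DenseNet:
    """Value network over the two adjustment directions."""
    return DenseNet((2 * n_metrics, *hidden, 2), seed=seed, leaky_slope=0.1)


def structure_coded_vector(s: np.ndarray, p: int, mapping: list[np.ndarray]) -> np.ndarray:
    """Keep the scores of slot ``p``'s metrics, zero everything else.

    The result has the same dimension as ``s`` and flags the chosen slot to
    the action network.
    """
    s = np.asarray(s, dtype=float).ravel()
    idx = np.asarray(mapping[p], dtype=int)
    if idx.size == 0:
        raise ValueError(f"priority slot {p} maps to no metrics")
    out = np.zeros_like(s)
    out[idx] = s[idx]
    return out


def _check_finite(q: np.ndarray, net_name: str) -> None:
    if not np.all(np.isfinite(q)):
        raise FloatingPointError(f"{net_name} produced non-finite values: {q}")


def select_tpp(s: np.ndarray, net: DenseNet) -> int:
    """Greedy slot choice: argmax of the parameter net; ties -> lowest index."""
    s = np.asarray(s, dtype=float).ravel()
    if not np.all(np.isfinite(s)):
        raise ValueError("state contains non-finite entries")
    q = net.forward(s)
    _check_finite(q, "parameter net")
    return int(np.argmax(q))


def action_net_input(s: np.ndarray, p: int, mapping: list[np.ndarray]) -> np.ndarray:
    return np.concatenate([structure_coded_vector(s, p, mapping), np.asarray(s, dtype=float).ravel()])


def select_action(s: np.ndarray, p: int, net: DenseNet, mapping: list[np.ndarray]) -> int:
    """Greedy direction choice; ties -> increase."""
    q = net.forward(action_net_input(s, p, mapping))
    _check_finite(q, "action net")
    return int(np.argmax(q))


def adaptive_step_size(last_relative_improvement: float | None) -> float:
    """6 priority points after a > 20% score improvement, else 3.

    The first adjustment of an episode (no previous improvement) uses the
    large step.
    """
    if last_relative_improvement is None:
        return STEP_LARGE
    if not np.isfinite(last_relative_improvement):
        raise ValueError("relative improvement must be finite")
    return STEP_LARGE if last_relative_improvement > STEP_CRITERION else STEP_SMALL


def apply_adjustment(pv: PriorityVector, p: int, action: int, step: float) -> PriorityVector:
    """Move slot ``p`` by +/- step, clamped to the priority bounds."""
    if action not in (INCREASE, DECREASE):
        raise ValueError(f"action must be {INCREASE} (increase) or {DECREASE} (decrease)")
    delta = step if action == INCREASE else -step
    return pv.replace_slot(p, pv[p] + delta)


@dataclass
class PlannerPolicy:
    """Greedy two-level policy bundling the nets with their state scaling.

    Scores are divided by their per-metric maxima before entering the nets so
    heterogeneous point budgets do not dominate the input scale.
    """

    parameter_net: DenseNet
    action_net: DenseNet
    mapping: list[np.ndarray]
    max_points: np.ndarray

    @classmethod
    def fresh(cls, config: ScoringConfig, seed: int = 0,
              hidden: tuple[int, ...] = DEFAULT_HIDDEN) -> "PlannerPolicy":
        mapping = config.tpp_index_map()
        n = len(config.metrics)
        return cls(
            parameter_net=make_parameter_net(seed=seed, hidden=hidden, n_metrics=n),
            action_net=make_action_net(seed=seed + 1, hidden=hidden, n_metrics=n),
            mapping=mapping,
            max_points=config.max_points,
        )

    def normalize(self, s: np.ndarray) -> np.ndarray:
        return np.asarray(s, dtype=float).ravel() / self.max_points

    def act(self, s: np.ndarray) -> tuple[int, int]:
        sn = self.normalize(s)
        p = select_tpp(sn, self.parameter_net)
        a = select_action(sn, p, self.action_net, self.mapping)
        return p, a

    def save(self, path) -> None:
        payload: dict[str, np.ndarray] = {"max_points": self.max_points,
                                          "n_slots": np.array(len(self.mapping))}
        for i, idx in enumerate(self.mapping):
            payload[f"map{i}"] = np.asarray(idx, dtype=int)
        for key, val in self.parameter_net.state_dict().items():
            payload["S_" + key] = val
        for key, val in self.action_net.state_dict().items():
            payload["A_" + key] = val
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "PlannerPolicy":
        with np.load(path) as z:
            data = {k: z[k] for k in z.files}
        n_slots = int(data["n_slots"])
        return cls(
            parameter_net=DenseNet.from_state_dict(
                {k[2:]: v for k, v in data.items() if k.startswith("S_")}),
            action_net=DenseNet.from_state_dict(
                {k[2:]: v for k, v in data.items() if k.startswith("A_")}),
            mapping=[data[f"map{i}"] for i in range(n_slots)],
            max_points=data["max_points"],
        )
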