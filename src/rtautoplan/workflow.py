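"""The closed auto-planning loop: initialize, optimize, score, adjust, repeat.

``initialize_plan`` builds the whole planning problem from configuration:
phantom generation, auxiliary-structure derivation, influence matrix,
objective binding, a first optimization and the baseline score.
``PlanningEnv`` wraps the problem as an episodic environment whose action is
(priority slot, direction); ``run_autoplanning`` drives it with any policy
and records a per-step decision trace.

The environment re-optimizes from a fixed deterministic initial fluence, so
the plan state is a pure function of the eight adjustable priorities.  That
keeps the decision process Markov in the priority vector and lets repeated
visits to the same priorities be served from a cache.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Protocol

import numpy as np
import pandas as pd

from .agent import (
    DECREASE,
    INCREASE,
    N_TPPS,
    adaptive_step_size,
    apply_adjustment,
)
from .dose import InfluenceMatrix, build_influence_matrix, compute_dose
from .geometry import (
    PhantomSpec,
    StructureSet,
    derive_auxiliary_structures,
    generate_phantom,
    mini_phantom_spec,
)
from .objectives import (
    ObjectiveSet,
    PriorityVector,
    apply_priorities,
    initial_priority_vector,
    load_objective_template,
)
from .optimizer import optimize_fluence
from .scoring import PlanScore, ScoringConfig, load_scoring_config, score_plan

__all__ = [
    "PlanState",
    "PlanRecord",
    "PlanningEnv",
    "initialize_plan",
    "run_autoplanning",
    "lookahead_oracle_agent",
    "LookaheadOraclePolicy",
    "RandomPolicy",
]


@dataclass
class PlanState:
    """Everything the loop needs: geometry, dose operator, objectives, plan."""

    structures: StructureSet
    influence: InfluenceMatrix
    template: ObjectiveSet
    scoring: ScoringConfig
    priorities: PriorityVector
    x0: np.ndarray
    fluence: np.ndarray
    dose: np.ndarray
    score: PlanScore
    step_index: int = 0
    solver_max_iters: int = 120
    solver_tol: float = 1e-5


def initialize_plan(
    phantom_spec: PhantomSpec | None = None,
    objective_template: ObjectiveSet | str | None = None,
    scoring_config: ScoringConfig | str | None = None,
    initial_priorities: PriorityVector | None = None,
    n_beams: int = 5,
    beamlet_width_mm: float = 8.0,
    solver_max_iters: int = 120,
    solver_tol: float = 1e-5,
) -> PlanState:
    """Set up the planning problem and solve the baseline plan.

    Stages (each failure is reported with its stage name): phantom
    generation, auxiliary structures, influence matrix, objective binding,
    baseline optimization, baseline scoring.
    """
    spec = phantom_spec if phantom_spec is not None else mini_phantom_spec()

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"plan initialization failed at stage {name!r}: {exc}") from exc

    ss = stage("phantom", lambda: derive_auxiliary_structures(generate_phantom(spec)))
    if isinstance(objective_template, (str,)) or objective_template is None:
        template = stage("objective template", lambda: load_objective_template(objective_template))
    else:
        template = objective_template
    if isinstance(scoring_config, (str,)) or scoring_config is None:
        scoring = stage("scoring config", lambda: load_scoring_config(scoring_config))
    else:
        scoring = scoring_config
    pv = initial_priorities if initial_priorities is not None else initial_priority_vector(template)

    influence = stage(
        "influence matrix",
        lambda: build_influence_matrix(ss, n_beams=n_beams, beamlet_width_mm=beamlet_width_mm),
    )
    oset = stage("objective binding", lambda: apply_priorities(template, pv))

    # deterministic initial fluence: uniform weights scaled so the mean
    # PTV63 dose of A@1 matches the top prescription level
    ones = np.ones(influence.n_beamlets)
    d1 = compute_dose(influence, ones)
    m = d1[ss["PTV63"].ravel()].mean()
    if m <= 0:
        raise RuntimeError("plan initialization failed at stage 'initial fluence': "
                           "no dose reaches PTV63")
    rx_top = max(spec.prescription_levels_cGy)
    x0 = ones * (rx_top / m)

    res = stage(
        "baseline optimization",
        lambda: optimize_fluence(influence, oset, ss, x0,
                                 max_iters=solver_max_iters, tol=solver_tol),
    )
    dose = compute_dose(influence, res.x)
    score = stage("baseline scoring", lambda: score_plan(dose, ss, scoring))
    return PlanState(
        structures=ss,
        influence=influence,
        template=template,
        scoring=scoring,
        priorities=pv,
        x0=x0,
        fluence=res.x,
        dose=dose,
        score=score,
        solver_max_iters=solver_max_iters,
        solver_tol=solver_tol,
    )


class PlanningEnv:
    """Episodic wrapper: actions are (priority slot, direction) pairs.

    The reward is the plan-score change; the state is the 21-entry score
    vector.  Evaluations are cached by priority vector (the dynamics are a
    deterministic function of it), which makes training loops cheap.
    """

    def __init__(self, state: PlanState, max_steps: int = 10,
                 reoptimize_iters: int | None = 60):
        self.base = state
        self.max_steps = max_steps
        self.reoptimize_iters = (state.solver_max_iters if reoptimize_iters is None
                                 else reoptimize_iters)
        self._cache: dict[tuple[float, ...], PlanScore] = {}
        self.tpp_metric_indices = state.scoring.tpp_index_map()
        self.score_max_points = state.scoring.max_points
        self.n_tpps = N_TPPS
        self.priorities = state.priorities
        self.last_rel_improvement: float | None = None
        self._step = 0
        # note: the baseline is evaluated with the env's own solver budget
        # (not seeded from state.score) so all cached scores are consistent
        self._psi = self.evaluate_priorities(state.priorities).total

    def evaluate_priorities(self, pv: PriorityVector) -> PlanScore:
        key = pv.p
        if key not in self._cache:
            oset = apply_priorities(self.base.template, pv)
            res = optimize_fluence(
                self.base.influence, oset, self.base.structures, self.base.x0,
                max_iters=self.reoptimize_iters, tol=self.base.solver_tol,
            )
            dose = compute_dose(self.base.influence, res.x)
            self._cache[key] = score_plan(dose, self.base.structures, self.base.scoring)
        return self._cache[key]

    def reset(self) -> np.ndarray:
        self.priorities = self.base.priorities
        self.last_rel_improvement = None
        self._step = 0
        score = self.evaluate_priorities(self.priorities)
        self._psi = score.total
        return score.vector.copy()

    def current_step_size(self) -> float:
        return adaptive_step_size(self.last_rel_improvement)

    def step(self, p: int, a: int) -> tuple[np.ndarray, float, bool, dict]:
        step_size = self.current_step_size()
        self.priorities = apply_adjustment(self.priorities, p, a, step_size)
        score = self.evaluate_priorities(self.priorities)
        r = score.total - self._psi
        self.last_rel_improvement = r / max(self._psi, 1.0)
        self._psi = score.total
        self._step += 1
        done = self._step >= self.max_steps
        info = {"psi": score.total, "step_size": step_size,
                "priorities": self.priorities}
        return score.vector.copy(), r, done, info


class Policy(Protocol):
    def act(self, s: np.ndarray) -> tuple[int, int]: ...


class RandomPolicy:
    """Uniform (slot, direction) baseline policy."""

    def __init__(self, seed: int = 0):
        self._rng = np.random.default_rng(seed)

    def act(self, s: np.ndarray) -> tuple[int, int]:
        return int(self._rng.integers(N_TPPS)), int(self._rng.integers(2))


class LookaheadOraclePolicy:
    """Exhaustive one-step lookahead: try all 16 adjustments, keep the best.

    A test oracle for policy quality, feasible only at desk scale.  Ties
    break toward the lowest slot, then toward increase.
    """

    def __init__(self, env: PlanningEnv):
        self.env = env

    def act(self, s: np.ndarray) -> tuple[int, int]:
        step_size = self.env.current_step_size()
        best = None
        for p in range(N_TPPS):
            for a in (INCREASE, DECREASE):
                cand = apply_adjustment(self.env.priorities, p, a, step_size)
                psi = self.env.evaluate_priorities(cand).total
                if best is None or psi > best[0]:
                    best = (psi, p, a)
        return best[1], best[2]


def lookahead_oracle_agent(env: PlanningEnv) -> tuple[int, int]:
    """The (slot, direction) with maximal one-step plan score from ``env``."""
    return LookaheadOraclePolicy(env).act(None)


@dataclass
class PlanRecord:
    """Per-step decision trace; entry 0 is the pre-adjustment baseline."""

    entries: pd.DataFrame
    final_psi: float
    final_priorities: PriorityVector

    def to_json(self, path) -> None:
        self.entries.to_json(path, orient="records", indent=2)

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def run_autoplanning(
    state_or_env: PlanState | PlanningEnv,
    agent: Policy,
    max_steps: int = 10,
    no_improve_patience: int = 3,
) -> PlanRecord:
    """Drive the optimize -> score -> decide -> adjust loop with ``agent``.

    Stops at ``max_steps`` or after ``no_improve_patience`` consecutive
    steps without score improvement (set to 0 to disable early stopping).
    """
    if max_steps < 0:
        raise ValueError("max_steps must be >= 0")
    env = (state_or_env if isinstance(state_or_env, PlanningEnv)
           else PlanningEnv(state_or_env, max_steps=max(max_steps, 1)))
    env.max_steps = max(max_steps, 1)
    s = env.reset()
    psi = float(np.sum(s))
    rows = [dict(step=0, p=-1, direction="", step_size=0.0, r=0.0, psi=psi,
                 **{f"s{i}": v for i, v in enumerate(s)})]
    best = psi
    stall = 0
    for step in range(1, max_steps + 1):
        p, a = agent.act(s)
        s, r, done, info = env.step(p, a)
        rows.append(dict(step=step, p=p,
                         direction="increase" if a == INCREASE else "decrease",
                         step_size=info["step_size"], r=r, psi=info["psi"],
                         **{f"s{i}": v for i, v in enumerate(s)}))
        if info["psi"] > best + 1e-9:
            best = info["psi"]
            stall = 0
        else:
            stall += 1
            if no_improve_patience and stall >= no_improve_patience:
                break
        if done:
            break
    entries = pd.DataFrame(rows)
    return PlanRecord(entries=entries, final_psi=float(entries.psi.iloc[-1]),
                      final_priorities=env.priorities)
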