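# rtautoplan

Automated inverse treatment planning for head-and-neck (H&N) radiotherapy,
driven by a hierarchical deep-Q-learning agent — with everything it needs to
run on a desk: a synthetic voxel phantom, a linear beamlet dose engine, and a
priority-weighted fluence-map optimizer standing in for a clinical treatment
planning system (TPS).

## The problem

Inverse planning asks a planner to steer an optimizer: dose-volume and
mean-dose objectives (each a dose limit τᵢ, an optional volume Vᵢ, and a
weight λᵢ, the *priority*) are set, the TPS solves for beamlet fluence, the
planner inspects the dose-volume histograms, nudges the priorities, and
repeats until the plan is good.  This trial-and-error loop is slow and
planner-dependent — exactly the kind of sequential decision problem
reinforcement learning handles well.  This package implements that loop
end-to-end for an H&N-like geometry with four prescription levels
(63 / 60 / 57 / 54 Gy) and eight organs at risk, and trains an agent to run
it autonomously.  The intended audience is computational medical-physics and
RL researchers who want the full planning loop as a reproducible, clinically
shaped benchmark without commercial software or patient data.

## The model

- **Phantom** (`geometry`): seeded, jittered ellipsoid anatomy on a voxel
  grid; nested PTVs, organs at risk with the clinically decisive
  target/organ overlaps, and the 26 auxiliary planning structures planners
  actually build (organ-minus-PTV crops, a 5 mm cord expansion, 3 mm target
  boundary rings, avoidance shells).
- **Dose** (`dose`): d = A·x with a sparse influence matrix A from
  equispaced coplanar beams — exponential depth attenuation exp(−μ·depth)
  with a Gaussian-penumbra beamlet profile — plus normalization of a plan to
  a prescribed PTV coverage.
- **TPS emulator** (`objectives`, `optimizer`): 47 objectives over the 26
  planning structures (20 lower / 18 upper dose-volume, 9 mean-dose; 141
  parameters in total).  36 objectives are fixed a priori; 11 expose their
  priorities through 8 shared slots P1..P8.  The optimizer is deterministic
  projected gradient descent with Armijo backtracking on the standard
  dose-volume-constraint surrogate penalty.
- **Plan score** (`scoring`): 21 piecewise-linear metrics (coverage,
  hotspot, organ sparing) with maxima summing to 150 points; the score
  vector is the agent's state s and the reward is r = ψ(d′) − ψ(d).
- **Agent** (`agent`, `training`): a parameter net S(s, p; θ_S) scores the 8
  adjustable priorities, an action net A(s, p, a; θ_A) picks the direction
  on a structure-coded input; both are 3-hidden-layer MLPs (Leaky ReLU,
  slope 0.1).  Step size is rule-based: ±6 after a >20% score improvement,
  else ±3.  Training alternates TD regression of A toward
  r + γ·max_p S(s′, p) with supervised regression of S toward max_a A,
  using ε-greedy exploration (ε = max(0.1, 0.99/EPI)) and experience replay.
- **Statistics** (`evaluation`): paired one-sided non-inferiority t-tests
  and comparison reports for plan-vs-plan evaluation.

## Worked example

```python
from rtautoplan.geometry import mini_phantom_spec
from rtautoplan.workflow import (initialize_plan, PlanningEnv,
                                 LookaheadOraclePolicy, run_autoplanning)

state = initialize_plan(mini_phantom_spec())        # 32x32 phantom, 5 beams
env = PlanningEnv(state, max_steps=10)
record = run_autoplanning(env, LookaheadOraclePolicy(env),
                          max_steps=10, no_improve_patience=0)
print(record.entries[["step", "p", "direction", "step_size", "r", "psi"]])
```

prints the decision trace of an automated planning session (slot indices
are 0-based, so `p = 2` is priority slot P3):

```
 step  p direction  step_size         r       psi
    0 -1                  0.0  0.000000 62.445550
    1  2  increase        6.0  1.069845 63.515395
    2  1  increase        3.0  0.199311 63.714706
    3  3  increase        3.0  0.107793 63.822499
    4  2  increase        3.0  0.608125 64.430624
    ...
```

The baseline plan scores ψ = 62.45 of 150; raising the right-parotid and
left-parotid priorities (P3, P2, P4) buys about two points of plan quality
within four adjustments, after which the one-step landscape is exhausted.
The same loop accepts a trained `PlannerPolicy` instead of the oracle; see
`rtautoplan train --help` and `rtautoplan plan --help` for the command-line
version of this workflow.

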