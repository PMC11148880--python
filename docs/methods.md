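# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `rtautoplan`, in the spirit of a package methods
appendix.  It states nothing the test suite or `scripts/acceptance.py` does
not itself compute.

## The planning problem being emulated

Clinical inverse planning for head-and-neck radiotherapy optimizes beamlet
fluence x ≥ 0 so the dose d = A·x covers four nested planning target
volumes (PTV63/60/57/54, prescriptions 6300–5400 cGy) while sparing the
parotid glands, spinal cord, brainstem, esophagus, oral cavity, pharyngeal
constrictor and brachial plexus.  A planner expresses this as weighted
objectives and iteratively re-weights them.  The package reproduces that
loop: the objective template carries 47 objectives over 26 planning
structures (20 lower dose-volume, 18 upper dose-volume, 9 mean-dose; 3
parameters each, 141 in total).  36 objectives are frozen at expert-style
values; the remaining 11 — all on parotids, oral cavity, constrictor and
brachial plexus — share 8 priority slots P1..P8, three of them because an
`_opti` auxiliary inherits its parent organ's priority.  The eight slots
are the agent's action space.

## Synthetic phantom

The phantom is a seeded, jittered ellipsoid geometry on a single axial
slab, not anatomical CT.  Positions and semi-axes are specified as
fractions of the body's semi-axes, so the same layout discretizes onto any
grid.  The layout realizes the overlap topology that makes H&N planning
hard — PTV54 intersects oral cavity, constrictor, both parotids and
esophagus; PTV57 the constrictor, left parotid and brachial plexus; PTV60
the oral cavity, left parotid and constrictor; PTV63 the constrictor and
brachial plexus — and generation fails loudly (`InfeasibleGeometryError`)
if a grid is too coarse to realize every required intersection.  Nesting is
enforced by construction (each PTV is unioned with the next-higher level;
CTVs are 2.5 mm erosions of their PTVs, falling back to the PTV on very
coarse grids).

Two grids are packaged: `mini_phantom_spec()` (32×32×1 voxels at 5 mm, the
training environment) and `default_phantom_spec()` (64×64×1 at 3.5 mm).
The structure algebra works in physical millimetres on voxel centers:
`expand` thresholds the Euclidean distance transform at the margin
(center-to-center); `erode`/`inner_ring` subtract half a voxel spacing from
the inside distance so they measure distance to the mask *surface* — this
keeps a 3 mm ring nonempty on the 5 mm grid, where the center-to-center
reading would return the empty set.  The three avoidance regions are
geometric stand-ins (posterior band, 6 mm peri-oral shell minus PTVs,
antero-lateral tube minus PTVs) for shells a dosimetrist would sculpt by
hand; their exact clinical shapes are not published anywhere we could
transcribe from.

## Dose engine

Photon physics is reduced to what the planning loop exercises:
exp(−μ·depth) depth attenuation (μ = 0.005/mm, a 6 MV-like value) along
each of 5 equispaced coplanar beams, and a lateral erf profile from
integrating a Gaussian penumbra (σ = 4 mm) over the beamlet width (8 mm
default).  Depth is the in-body path length found by ray marching at half
the finest voxel spacing.  Beamlets tile the PTV-union projection plus a
5 mm margin; kernel values below 10⁻⁴ are truncated to keep A sparse.
Fluence units are arbitrary — plans are compared after optimization or
normalized to PTV coverage (`normalize_to_coverage` rescales by
rx / (1−coverage)-quantile of PTV dose, ties toward the higher quantile).
Dose vectors live on the full flattened grid with zeros outside the body,
so structure masks index them directly.

## Optimizer and penalty surrogate

The objective is Σᵢ λᵢ·penᵢ(d) with per-voxel-normalized penalties.  Mean
objectives use (max(0, mean − τ))².  Dose-volume constraints use the
canonical surrogate: an upper DVC (τ, V) penalizes only voxels with dose in
(τ, D_V], where D_V is the current dose at volume V (the maximum when
V = 0); the rule is mirrored for lower DVCs.  Active sets are recomputed at
every function evaluation.  The solver is projected gradient descent with
Armijo backtracking (c = 10⁻⁴), a growing/backtracking step size, and a
hard iteration cap; only strictly decreasing steps are accepted, so the
objective trace is non-increasing by construction, and there is no
randomness anywhere in the solve.  The initial fluence is uniform, scaled
so the mean PTV63 dose of A·1 equals the top prescription.  Priorities are
bounded to [1, 100], bracketing the fixed template values (30–100).

## Plan score

The score ψ(d) ∈ [0, 150] sums 21 piecewise-linear metrics: PTV/CTV
coverage at prescription, body and PTV63 hotspots (D[0.03cc]), parotid
V30Gy and mean dose, cord/brainstem/brachial-plexus near-maximum doses,
oral-cavity/esophagus/constrictor mean doses, and a 50 Gy body-spillage
volume.  The metric set and clinical goals (≥95% coverage for the 63/60 Gy
targets, ≥90% for 57/54 Gy, hotspot below 69 Gy) follow standard H&N
plan-quality practice; the exact breakpoints are this package's own linear
ramps between a full-credit and a zero-credit level, since no published
breakpoint table was available to transcribe.  Metrics are evaluated on raw
voxel doses (not the binned DVH); `dose_at_volume` resolves ties toward the
lower dose and `volume_at_dose` counts voxels at or above threshold — both
conservative for organ limits.  The 21-entry score vector is the RL state;
the reward is the score change.

## Agent and training

Parameter-Net (21 → 128 → 64 → 32 → 8) and Action-Net (42 → 128 → 64 → 32
→ 2) are fully connected with Leaky ReLU (slope 0.1) after each hidden
layer; scores are divided by their per-metric maxima before entering the
nets.  The action net's input concatenates the state with a structure-coded
copy (only the chosen slot's metrics kept, all else zeroed).  Ties break
deterministically (lowest slot; increase).  The slot→metric map ships in
the scoring configuration.  The step-size rule is fixed, not learned: 6
after a relative score improvement above 20% on the previous adjustment
(improvement measured relative to max(ψ_prev, 1)), else 3; the first
adjustment of an episode uses 6.

Training is Q-learning with experience replay (uniform sampling, capacity
10⁴, batch 32) and ε = max(0.1, 0.99/episode).  The two nets alternate:
each environment step performs one Adam TD update of the action net toward
r + γ·max_p S(s′, p) (γ = 0.9), and every fifth such update is followed by
one supervised update of the parameter net toward max_a A(s, p, a) on the
same batch.  The Adam learning rate defaults to 10⁻³ — at desk scale a few
thousand replay updates must suffice, and smaller rates demonstrably
underfit within that budget.  Networks are numpy with manual
backpropagation; every forward/backward pass and every sampling decision is
driven by explicit seeded generators, so a training run is a pure function
of (environment, hyperparameters, seed).

## Planning environment and caching

`PlanningEnv` re-optimizes from the same deterministic initial fluence at
every step (cold start, 60 iterations by default) rather than warm-starting
from the previous solution.  This is a deliberate modelling choice: with a
cold start the optimized plan — and hence the state and reward — is a pure
function of the eight priorities, which keeps the decision process Markov
in the priority vector and lets repeated visits be served from a cache.
Warm starting (supported by `run_autoplanning` via the underlying solver)
would couple the state to the visit path.  The baseline is evaluated under
the same solver budget as every other state so that rewards are internally
consistent.  The default episode is 10 adjustments, and the planning loop
optionally stops after 3 consecutive non-improving steps.

## Problem sizes and verification

The packaged training environment is the 32×32 phantom with 5 beams
(~50–60 beamlets) — small enough that the exhaustive one-step-lookahead
oracle (all 16 slot/direction candidates per step) is computable and that a
10-seed training study finishes in minutes.  The acceptance suite trains
250-episode × 10-step runs on ten seeds and requires the greedy policy's
fixed-length final score to beat both the baseline and the mean final score
of a uniform-random policy, and to stay within 10% of the lookahead
oracle, on at least 8 of 10 seeds.  All structure algebra, metric, penalty
and tabular-Q kernels are verified against exhaustive brute-force oracles
on small instances, and tabular Q-learning is checked against value
iteration on a 5-state MDP.  The non-inferiority test (one-sided paired t;
margin 0 by default, i.e. a superiority test, because no clinical margin
convention exists to import) is calibrated under its null by simulation.

## What the synthetic setting does and does not show

Passing tests demonstrate that the decision architecture learns to operate
a deterministic, low-dimensional TPS emulator whose trade-offs are
H&N-shaped.  They do not demonstrate clinical plan quality: the dose model
has no heterogeneity, scatter or delivery constraints; the phantom has no
real anatomy; the score breakpoints are package-chosen; plan-score levels
are therefore not comparable to clinical scores.  Single-slab geometry also
makes some target/organ conflicts milder than in 3D.  Known limitations:
the optimizer's DVC surrogate is nonconvex (solutions depend on the
iteration budget, which is why the environment fixes it), and the trained
policy is specific to the phantom seed and scoring configuration it was
trained on.
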