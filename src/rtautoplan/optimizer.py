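"""Deterministic projected-gradient fluence-map optimization.

Minimizes the priority-weighted objective penalty over nonnegative beamlet
fluence with projected gradient descent and Armijo backtracking.  The
dose-volume active sets are recomputed at every function evaluation, which is
the standard treatment of the DVC surrogate; only strictly decreasing steps
are accepted, so the objective trace is non-increasing by construction.
There is no randomness anywhere: identical inputs give identical iterates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .dose import InfluenceMatrix
from .geometry import StructureSet
from .objectives import BoundObjectiveSet, ObjectiveSet

__all__ = ["SolverResult", "optimize_fluence"]


@dataclass
class SolverResult:
    x: np.ndarray
    objective_trace: np.ndarray
    n_iters: int
    converged: bool

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


def optimize_fluence(
    influence: InfluenceMatrix | sparse.spmatrix,
    oset: ObjectiveSet,
    ss: StructureSet,
    x0: np.ndarray,
    max_iters: int = 200,
    tol: float = 1e-8,
    armijo_c: float = 1e-4,
    max_backtracks: int = 40,
) -> SolverResult:
    """Projected-gradient descent on the plan objective under x >= 0.

    ``tol`` is a relative decrease threshold: iteration stops when an accepted
    step improves the objective by less than ``tol * (1 + f)``.
    Returns the final fluence plus the (non-increasing) objective trace.
    """
    A = influence.entries if isinstance(influence, InfluenceMatrix) else influence
    x = np.asarray(x0, dtype=float).ravel().copy()
    if x.shape[0] != A.shape[1]:
        raise ValueError(f"x0 length {x.shape[0]} != beamlet count {A.shape[1]}")
    if np.any(x < 0):
        raise ValueError("x0 must be nonnegative")

    if not oset.objectives:
        return SolverResult(x, np.array([0.0]), 0, True)

    bound = BoundObjectiveSet(oset, ss)
    AT = A.T.tocsr() if sparse.issparse(A) else A.T

    def f_only(xv: np.ndarray) -> float:
        return bound.value(np.asarray(A @ xv).ravel())[0]

    d = np.asarray(A @ x).ravel()
    f, gd = bound.value_and_grad(d)
    if not np.isfinite(f):
        raise FloatingPointError("non-finite objective at x0")
    trace = [f]
    t = None
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        g = np.asarray(AT @ gd).ravel()
        gnorm2 = float(g @ g)
        if gnorm2 == 0.0:
            converged = True
            break
        if t is None:
            # initial step: unit relative move in x
            t = (np.abs(x).max() + 1.0) / np.sqrt(gnorm2)
        else:
            t *= 2.0  # let the accepted step grow back

        accepted = False
        for _ in range(max_backtracks):
            x_new = np.maximum(x - t * g, 0.0)
            decrease_pred = float(g @ (x - x_new))
            f_new = f_only(x_new)
            if not np.isfinite(f_new):
                raise FloatingPointError("non-finite objective during line search")
            if f_new <= f - armijo_c * decrease_pred and f_new < f:
                accepted = True
                break
            t /= 2.0
        if not accepted:
            converged = True
            break

        improvement = f - f_new
        x = x_new
        d = np.asarray(A @ x).ravel()
        f, gd = bound.value_and_grad(d)
        trace.append(f)
        if improvement <= tol * (1.0 + abs(f)):
            converged = True
            break

    return SolverResult(x, np.asarray(trace), it, converged)
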