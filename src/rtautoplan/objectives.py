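"""Inverse-planning objective template: dose-volume and mean-dose penalties.

Each objective i carries a dose limit tau_i, a volume V_i (dose-volume
objectives only) and a weighting factor lambda_i (the "priority").  Targets
get lower objectives (penalize underdose) plus an upper cap for homogeneity;
organs at risk get upper and mean objectives.  Most priorities are fixed a
priori; eleven objectives expose their priorities through eight shared slots
P1..P8, which are the knobs the planning agent turns.

The penalty functional is the canonical dose-volume-constraint surrogate: an
upper DVC (tau, V) penalizes only voxels with dose in (tau, D_V], where D_V
is the current dose received by the hottest V% of the structure (symmetric
rule for lower DVCs); a mean objective penalizes the squared excess of the
structure mean over tau.  Penalties are normalized per voxel so priorities
are comparable across structure sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .geometry import StructureSet

__all__ = [
    "PlanObjective",
    "ObjectiveSet",
    "PriorityVector",
    "PRIORITY_SLOTS",
    "load_objective_template",
    "apply_priorities",
    "objective_value",
    "BoundObjectiveSet",
    "template_summary",
]

OBJECTIVE_TYPES = ("lower", "upper", "mean")
PRIORITY_SLOTS = tuple(f"P{k}" for k in range(1, 9))


@dataclass(frozen=True)
class PlanObjective:
    """One planning objective (tau_i, V_i, lambda_i, type, structure)."""

    structure: str
    dose_cGy: float
    objective_type: str
    volume_pct: float | None = None
    priority: float | None = None
    placeholder: str | None = None

    def __post_init__(self) -> None:
        if self.objective_type not in OBJECTIVE_TYPES:
            raise ValueError(f"unknown objective type {self.objective_type!r}")
        if self.dose_cGy < 0:
            raise ValueError("dose limit must be >= 0")
        if self.objective_type in ("lower", "upper"):
            if self.volume_pct is None or not 0 <= self.volume_pct <= 100:
                raise ValueError(
                    f"{self.objective_type} objective on {self.structure!r} "
                    f"needs volume_pct in [0, 100]"
                )
        if self.placeholder is not None and self.placeholder not in PRIORITY_SLOTS:
            raise ValueError(f"priority placeholder must be one of {PRIORITY_SLOTS}")
        if self.placeholder is None and self.priority is None:
            raise ValueError(f"objective on {self.structure!r} has neither priority nor placeholder")
        if self.priority is not None and self.priority < 0:
            raise ValueError("priority must be >= 0")

    @property
    def is_adjustable(self) -> bool:
        return self.placeholder is not None


@dataclass
class ObjectiveSet:
    """Ordered objectives plus the placeholder -> objective-index map."""

    objectives: list[PlanObjective]
    priority_bounds: tuple[float, float] = (1.0, 100.0)
    initial_priorities: dict[str, float] = field(default_factory=dict)

    @property
    def adjustable_map(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, obj in enumerate(self.objectives):
            if obj.placeholder is not None:
                out.setdefault(obj.placeholder, []).append(i)
        return out

    def structures(self) -> list[str]:
        seen: dict[str, None] = {}
        for obj in self.objectives:
            seen.setdefault(obj.structure)
        return list(seen)

    def validate(self) -> None:
        amap = self.adjustable_map
        missing = [p for p in PRIORITY_SLOTS if p not in amap]
        if missing:
            raise ValueError(f"placeholders with no objective: {missing}")


@dataclass(frozen=True)
class PriorityVector:
    """Numeric priorities for the eight adjustable slots P1..P8."""

    p: tuple[float, ...]
    bounds: tuple[float, float] = (1.0, 100.0)

    def __post_init__(self) -> None:
        if len(self.p) != len(PRIORITY_SLOTS):
            raise ValueError(f"expected {len(PRIORITY_SLOTS)} priorities, got {len(self.p)}")
        lo, hi = self.bounds
        for v in self.p:
            if not lo <= v <= hi:
                raise ValueError(f"priority {v} outside bounds [{lo}, {hi}]")
        object.__setattr__(self, "p", tuple(float(v) for v in self.p))

    def __getitem__(self, key: int | str) -> float:
        if isinstance(key, str):
            key = PRIORITY_SLOTS.index(key)
        return self.p[key]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(PRIORITY_SLOTS, self.p))

    def replace_slot(self, slot: int, value: float) -> "PriorityVector":
        lo, hi = self.bounds
        value = float(np.clip(value, lo, hi))
        p = list(self.p)
        p[slot] = value
        return PriorityVector(tuple(p), self.bounds)


def default_template_path() -> Path:
    return Path(str(resources.files("rtautoplan.data") / "objectives_hn.yaml"))


def load_objective_template(path: str | Path | None = None) -> ObjectiveSet:
    """Load and validate the packaged (or a user) objective template."""
    path = default_template_path() if path is None else Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "objectives" not in raw:
        raise ValueError(f"template {path} has no 'objectives' list")
    bounds = tuple(float(v) for v in raw.get("priority_bounds", (1, 100)))
    objectives: list[PlanObjective] = []
    for k, entry in enumerate(raw["objectives"]):
        try:
            pr = entry.get("priority")
            placeholder = None
            priority = None
            if isinstance(pr, str):
                placeholder = pr
            elif pr is not None:
                priority = float(pr)
            objectives.append(
                PlanObjective(
                    structure=str(entry["structure"]),
                    dose_cGy=float(entry["dose_cGy"]),
                    objective_type=str(entry["type"]),
                    volume_pct=(None if entry.get("volume_pct") is None
                                else float(entry["volume_pct"])),
                    priority=priority,
                    placeholder=placeholder,
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"objective #{k} in {path} is invalid: {exc}") from exc
    init = {str(k): float(v) for k, v in (raw.get("initial_priorities") or {}).items()}
    oset = ObjectiveSet(objectives=objectives, priority_bounds=bounds,  # type: ignore[arg-type]
                        initial_priorities=init)
    oset.validate()
    return oset


def apply_priorities(oset: ObjectiveSet, pv: PriorityVector) -> ObjectiveSet:
    """Resolve every placeholder Pk to pv[k]; fixed objectives untouched.

    Objectives sharing a placeholder are updated atomically; idempotent.
    """
    lo, hi = oset.priority_bounds
    for v in pv.p:
        if not lo <= v <= hi:
            raise ValueError(f"priority {v} outside template bounds [{lo}, {hi}]")
    new = []
    for obj in oset.objectives:
        if obj.placeholder is not None:
            new.append(replace(obj, priority=pv[obj.placeholder]))
        else:
            new.append(obj)
    return ObjectiveSet(new, oset.priority_bounds, dict(oset.initial_priorities))


def initial_priority_vector(oset: ObjectiveSet) -> PriorityVector:
    """The template's shipped starting point for the adjustable priorities."""
    if not oset.initial_priorities:
        mid = (oset.priority_bounds[0] + oset.priority_bounds[1]) / 2.0
        return PriorityVector(tuple(mid for _ in PRIORITY_SLOTS), oset.priority_bounds)
    return PriorityVector(
        tuple(oset.initial_priorities[s] for s in PRIORITY_SLOTS), oset.priority_bounds
    )


# ---------------------------------------------------------------------------
# Penalty evaluation
# ---------------------------------------------------------------------------

class BoundObjectiveSet:
    """Objectives bound to a structure set for fast repeated evaluation."""

    def __init__(self, oset: ObjectiveSet, ss: StructureSet):
        self.oset = oset
        self._idx: list[np.ndarray] = []
        for obj in oset.objectives:
            if obj.priority is None:
                raise ValueError(
                    f"objective on {obj.structure!r} has unresolved placeholder "
                    f"{obj.placeholder!r}; call apply_priorities first"
                )
            if obj.structure not in ss:
                raise KeyError(
                    f"objective references structure {obj.structure!r} absent "
                    f"from the structure set"
                )
            self._idx.append(np.flatnonzero(ss[obj.structure].ravel()))

    def value(self, d: np.ndarray) -> tuple[float, np.ndarray]:
        per = np.array([self._penalty(d, i, grad=None) for i in range(len(self._idx))])
        weights = np.array([o.priority for o in self.oset.objectives])
        return float(weights @ per), per

    def value_and_grad(self, d: np.ndarray) -> tuple[float, np.ndarray]:
        grad = np.zeros_like(d)
        total = 0.0
        for i, obj in enumerate(self.oset.objectives):
            total += obj.priority * self._penalty(d, i, grad=grad)
        return float(total), grad

    def _penalty(self, d: np.ndarray, i: int, grad: np.ndarray | None) -> float:
        obj = self.oset.objectives[i]
        idx = self._idx[i]
        n = idx.size
        if n == 0:
            return 0.0
        dv = d[idx]
        tau = obj.dose_cGy
        lam = obj.priority if grad is not None else 1.0

        if obj.objective_type == "mean":
            excess = dv.mean() - tau
            if excess <= 0:
                return 0.0
            if grad is not None:
                grad[idx] += lam * 2.0 * excess / n
            return float(excess**2)

        v = obj.volume_pct
        if obj.objective_type == "upper":
            # D_V: dose at volume V% (max dose for V = 0); penalize voxels in
            # (tau, D_V] — only the excess that actually violates the DVC.
            k = int(np.ceil(v / 100.0 * n))
            d_v = dv.max() if k == 0 else np.partition(dv, n - k)[n - k]
            active = (dv > tau) & (dv <= d_v)
            diff = dv[active] - tau
        else:  # lower
            k = int(np.ceil(v / 100.0 * n))
            k = min(max(k, 1), n)
            d_v = np.partition(dv, n - k)[n - k]
            active = (dv < tau) & (dv >= d_v)
            diff = dv[active] - tau
        if diff.size == 0:
            return 0.0
        if grad is not None:
            grad[idx[active]] += lam * 2.0 * diff / n
        return float(np.sum(diff**2) / n)


def objective_value(
    d: np.ndarray, oset: ObjectiveSet, ss: StructureSet
) -> tuple[float, np.ndarray]:
    """Total weighted penalty sum(lambda_i * penalty_i(d)) and per-objective
    penalties (unweighted).  Zero total iff every objective is satisfied."""
    return BoundObjectiveSet(oset, ss).value(np.asarray(d, dtype=float).ravel())


def template_summary(oset: ObjectiveSet) -> dict[str, int]:
    """Configuration census: structure/objective/parameter counts."""
    objs = oset.objectives
    by_type = {t: sum(1 for o in objs if o.objective_type == t) for t in OBJECTIVE_TYPES}
    adjustable = [o for o in objs if o.is_adjustable]
    # auxiliaries that share a slot with an objective on a different structure
    shared_aux = 0
    amap = oset.adjustable_map
    for slot, idxs in amap.items():
        structs = {objs[i].structure for i in idxs}
        if len(structs) > 1:
            shared_aux += sum(1 for s in structs if s.endswith("_opti"))
    return {
        "n_structures": len(oset.structures()),
        "n_objectives": len(objs),
        "n_lower": by_type["lower"],
        "n_upper": by_type["upper"],
        "n_mean": by_type["mean"],
        "n_parameter_slots": 3 * len(objs),
        "n_fixed": len(objs) - len(adjustable),
        "n_adjustable": len(adjustable),
        "n_shared_priority_aux": shared_aux,
        "n_priority_slots": len(amap),
    }
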