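"""DVHs, dosimetric metrics, the 21-component plan-quality score and reward.

The plan score psi(d) is a sum of piecewise-linear per-metric scores in the
style of the ProKnow system: each metric (a mean dose, a dose at volume, or a
volume at dose) is mapped through breakpoints onto [0, max_points], and the
21 default metrics have maxima summing to 150.  The per-metric score vector
is the state the planning agent observes; the reward for an adjustment is the
change in total score, r = psi(d') - psi(d).

Metrics are computed from raw voxel doses, not from the binned DVH curve, to
avoid discretization bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import StructureSet

__all__ = [
    "DVHCurve",
    "MetricSpec",
    "ScoringConfig",
    "PlanScore",
    "compute_dvh",
    "eval_metric",
    "score_metric",
    "score_plan",
    "reward",
    "load_scoring_config",
    "metric_report",
]

METRIC_KINDS = ("mean_dose", "dose_at_volume_cc", "dose_at_volume_pct", "volume_at_dose_pct")


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume histogram: volume (%) receiving >= each dose."""

    dose_bins_cGy: np.ndarray
    volume_pct: np.ndarray


def compute_dvh(d: np.ndarray, mask: np.ndarray, bin_width_cGy: float = 10.0) -> DVHCurve:
    """Cumulative volume-above-dose curve; V(0) = 100 for nonempty masks."""
    if bin_width_cGy <= 0:
        raise ValueError("bin width must be > 0")
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(d, dtype=float).ravel()[mask.ravel()]
    if vals.size == 0:
        raise ValueError("empty structure mask")
    top = max(float(vals.max()), bin_width_cGy)
    bins = np.arange(0.0, top + 2 * bin_width_cGy, bin_width_cGy)
    vol = np.array([(vals >= b).mean() * 100.0 for b in bins])
    return DVHCurve(dose_bins_cGy=bins, volume_pct=vol)


@dataclass(frozen=True)
class MetricSpec:
    """One scored dosimetric metric with piecewise-linear breakpoints."""

    name: str
    structure: str
    kind: str
    breakpoints: tuple[tuple[float, float], ...]
    max_points: float
    dose_cGy: float | None = None
    volume_cc: float | None = None
    volume_pct: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in METRIC_KINDS:
            raise ValueError(f"unknown metric kind {self.kind!r}")
        if self.max_points <= 0:
            raise ValueError("max_points must be > 0")
        vals = [v for v, _ in self.breakpoints]
        pts = [p for _, p in self.breakpoints]
        if len(vals) < 2 or any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError(f"breakpoints of {self.name!r} must be strictly increasing in value")
        if any(not 0 <= p <= self.max_points for p in pts):
            raise ValueError(f"breakpoint points of {self.name!r} outside [0, max_points]")
        diffs = np.diff(pts)
        if not (np.all(diffs >= 0) or np.all(diffs <= 0)):
            raise ValueError(f"breakpoint points of {self.name!r} must be monotone")


def eval_metric(d: np.ndarray, ss: StructureSet, spec: MetricSpec) -> float:
    """Evaluate a raw dosimetric metric on the plan dose."""
    vals = np.asarray(d, dtype=float).ravel()[ss[spec.structure].ravel()]
    if vals.size == 0:
        raise ValueError(f"metric {spec.name!r}: structure {spec.structure!r} is empty")
    if spec.kind == "mean_dose":
        return float(vals.mean())
    if spec.kind == "volume_at_dose_pct":
        return float((vals >= spec.dose_cGy).mean() * 100.0)
    if spec.kind == "dose_at_volume_pct":
        k = int(np.ceil(spec.volume_pct / 100.0 * vals.size))
        k = min(max(k, 1), vals.size)
        return float(np.sort(vals)[::-1][k - 1])
    # dose_at_volume_cc: max dose received by at least volume_cc of the structure
    vol_vox = ss.grid.voxel_volume_cc
    if spec.volume_cc > vals.size * vol_vox:
        raise ValueError(
            f"metric {spec.name!r}: requested {spec.volume_cc} cc exceeds "
            f"structure volume {vals.size * vol_vox:.3f} cc"
        )
    k = int(np.ceil(spec.volume_cc / vol_vox - 1e-9))
    k = min(max(k, 1), vals.size)
    return float(np.sort(vals)[::-1][k - 1])


def score_metric(value: float, spec: MetricSpec) -> float:
    """Piecewise-linear interpolation of the breakpoints, clamped to the ends."""
    xs = np.array([v for v, _ in spec.breakpoints])
    ps = np.array([p for _, p in spec.breakpoints])
    return float(np.interp(value, xs, ps))


@dataclass
class ScoringConfig:
    metrics: list[MetricSpec]
    tpp_metric_map: dict[str, list[str]] = field(default_factory=dict)

    @property
    def max_points(self) -> np.ndarray:
        return np.array([m.max_points for m in self.metrics])

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.metrics]

    def metric_indices(self, names: list[str]) -> np.ndarray:
        order = {n: i for i, n in enumerate(self.names)}
        return np.array([order[n] for n in names], dtype=int)

    def tpp_index_map(self) -> list[np.ndarray]:
        """Score-vector indices per adjustable priority slot, P1..P8 order."""
        out = []
        for k in range(1, len(self.tpp_metric_map) + 1):
            out.append(self.metric_indices(self.tpp_metric_map[f"P{k}"]))
        return out


def default_scoring_path() -> Path:
    return Path(str(resources.files("rtautoplan.data") / "scoring_hn.yaml"))


def load_scoring_config(path: str | Path | None = None) -> ScoringConfig:
    path = default_scoring_path() if path is None else Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "metrics" not in raw:
        raise ValueError(f"scoring config {path} has no 'metrics' list")
    metrics = []
    for k, entry in enumerate(raw["metrics"]):
        try:
            metrics.append(
                MetricSpec(
                    name=str(entry["name"]),
                    structure=str(entry["structure"]),
                    kind=str(entry["kind"]),
                    breakpoints=tuple((float(v), float(p)) for v, p in entry["breakpoints"]),
                    max_points=float(entry["max_points"]),
                    dose_cGy=(None if entry.get("dose_cGy") is None else float(entry["dose_cGy"])),
                    volume_cc=(None if entry.get("volume_cc") is None else float(entry["volume_cc"])),
                    volume_pct=(None if entry.get("volume_pct") is None else float(entry["volume_pct"])),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"metric #{k} in {path} is invalid: {exc}") from exc
    tmap = {str(k): [str(n) for n in v] for k, v in (raw.get("tpp_metric_map") or {}).items()}
    return ScoringConfig(metrics=metrics, tpp_metric_map=tmap)


@dataclass(frozen=True)
class PlanScore:
    """Total plan score psi plus the per-metric score vector (the RL state)."""

    total: float
    vector: np.ndarray
    values: np.ndarray
    names: tuple[str, ...]


def score_plan(d: np.ndarray, ss: StructureSet, config: ScoringConfig) -> PlanScore:
    """Evaluate and score every metric; total = sum of the vector."""
    values = np.empty(len(config.metrics))
    scores = np.empty(len(config.metrics))
    failed = []
    for i, spec in enumerate(config.metrics):
        if spec.structure not in ss:
            failed.append(f"{spec.name} (missing structure {spec.structure!r})")
            continue
        values[i] = eval_metric(d, ss, spec)
        scores[i] = score_metric(values[i], spec)
    if failed:
        raise KeyError("cannot score plan; failing metrics: " + "; ".join(failed))
    return PlanScore(
        total=float(scores.sum()),
        vector=scores,
        values=values,
        names=tuple(config.names),
    )


def reward(psi_prev: float, psi_new: float) -> float:
    """Plan-quality change r = psi(d') - psi(d)."""
    if not (np.isfinite(psi_prev) and np.isfinite(psi_new)):
        raise ValueError("plan scores must be finite")
    return float(psi_new) - float(psi_prev)


def metric_report(score: PlanScore, config: ScoringConfig) -> pd.DataFrame:
    """Per-metric table (metric, value, score, max) for export."""
    return pd.DataFrame(
        {
            "metric": list(score.names),
            "value": score.values,
            "score": score.vector,
            "max_points": config.max_points,
        }
    )
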