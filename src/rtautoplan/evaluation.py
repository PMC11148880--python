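"""Paired plan-comparison statistics and reporting.

The headline comparison between auto-planned and reference plans is a
one-sided paired non-inferiority t-test: H0 says the auto-planner's mean
score deficit exceeds the margin (inferior), H1 that it does not.  With the
default margin of 0 this degenerates to a one-sided superiority test.  No
multiple-testing correction is applied across per-metric tests; each p-value
is reported as-is.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PairedScores", "NonInferiorityResult", "noninferiority_test", "comparison_report"]


@dataclass(frozen=True)
class PairedScores:
    """Per-case scores for the auto-planner (a) and the reference arm (b)."""

    case_ids: tuple
    score_a: np.ndarray
    score_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.score_a, dtype=float)
        b = np.asarray(self.score_b, dtype=float)
        if not (len(self.case_ids) == a.size == b.size):
            raise ValueError("case ids and both score vectors must have equal length")
        if a.size < 2:
            raise ValueError("need at least 2 paired cases")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("scores must be finite")
        object.__setattr__(self, "score_a", a)
        object.__setattr__(self, "score_b", b)


class NonInferiorityResult(NamedTuple):
    p_value: float
    non_inferior: bool
    t_statistic: float
    mean_difference: float
    n: int


def noninferiority_test(ps: PairedScores, margin: float = 0.0,
                        alpha: float = 0.05) -> NonInferiorityResult:
    """One-sided paired t-test of H0: mean(a - b) <= -margin.

    Non-inferiority is concluded when p < alpha.  A zero-variance difference
    vector is handled explicitly: p = 0 if the mean difference beats the
    margin, else p = 1.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    diff = ps.score_a - ps.score_b
    n = diff.size
    shifted = diff + margin
    sd = shifted.std(ddof=1)
    mean = shifted.mean()
    if sd == 0.0:
        p = 0.0 if mean > 0 else 1.0
        t_stat = np.inf if mean > 0 else (-np.inf if mean < 0 else 0.0)
    else:
        t_stat = mean / (sd / np.sqrt(n))
        p = float(stats.t.sf(t_stat, df=n - 1))
    return NonInferiorityResult(
        p_value=float(p),
        non_inferior=bool(p < alpha),
        t_statistic=float(t_stat),
        mean_difference=float(diff.mean()),
        n=int(n),
    )


def comparison_report(
    ps: PairedScores,
    per_metric: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    margin: float = 0.0,
    alpha: float = 0.05,
    out_csv: str | Path | None = None,
    out_json: str | Path | None = None,
) -> pd.DataFrame:
    """Summary table (mean +/- sd per arm, p-value) per metric plus the total.

    ``per_metric`` maps metric name -> (values_a, values_b) aligned with
    ``ps.case_ids``.  Optionally written as CSV and JSON.
    """
    rows = []

    def row(name: str, a: np.ndarray, b: np.ndarray) -> dict:
        sub = PairedScores(ps.case_ids, a, b)
        res = noninferiority_test(sub, margin=margin, alpha=alpha)
        return dict(
            metric=name,
            mean_a=float(np.mean(a)), sd_a=float(np.std(a, ddof=1)),
            mean_b=float(np.mean(b)), sd_b=float(np.std(b, ddof=1)),
            mean_difference=res.mean_difference,
            p_value=res.p_value,
            non_inferior=res.non_inferior,
        )

    for name, (a, b) in (per_metric or {}).items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size != len(ps.case_ids) or b.size != len(ps.case_ids):
            raise ValueError(f"metric {name!r} is not aligned with the case ids")
        rows.append(row(name, a, b))
    rows.append(row("total", ps.score_a, ps.score_b))
    report = pd.DataFrame(rows)
    if out_csv is not None:
        report.to_csv(out_csv, index=False)
    if out_json is not None:
        Path(out_json).write_text(json.dumps(report.to_dict(orient="records"), indent=2))
    return report
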