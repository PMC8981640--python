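"""Kaplan-Meier estimation and log-rank comparison of predicted groups.

Patients predicted metastatic vs multiple-primary are compared on overall
survival: the product-limit (Kaplan-Meier) estimator per group, the median
survival time (smallest time at which the survival curve drops to <= 0.5)
with a Greenwood log(-log) 95% confidence interval, and the standard
two-group log-rank chi-square test (1 df, simultaneous-death tie
convention, two-sided p).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times

__all__ = [
    "Group",
    "SurvivalRecord",
    "KMEstimate",
    "km_estimate",
    "logrank_test",
    "read_records",
]


class Group(str, enum.Enum):
    METASTATIC = "metastatic"
    MULTIPLE_PRIMARY = "multiple_primary"


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time_months: float
    event: bool                      # True = death observed, False = censored
    group: Optional[Group] = None

    def __post_init__(self):
        if self.time_months <= 0:
            raise ValueError(f"time_months must be positive, got {self.time_months}")


@dataclass
class KMEstimate:
    """Step-function survival estimate with median and its 95% CI.

    ``median`` is ``math.inf`` when the curve never reaches 0.5
    (median not reached); the same convention applies to CI bounds.
    """

    times: np.ndarray          # event/censor times (step locations)
    survival: np.ndarray       # S(t) immediately after each time
    median: float
    median_ci: tuple[float, float]
    n: int
    n_events: int

    @property
    def median_reached(self) -> bool:
        return math.isfinite(self.median)

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function evaluation."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records: Sequence[SurvivalRecord], alpha: float = 0.05) -> KMEstimate:
    """Product-limit estimate over one set of records."""
    if not records:
        raise ValueError("km_estimate requires >= 1 record")
    times = np.array([r.time_months for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)

    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, events)
    sf = kmf.survival_function_
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = grid > 0
    return KMEstimate(
        times=grid[keep],
        survival=surv[keep],
        median=float(kmf.median_survival_time_),
        median_ci=(lo, hi),
        n=len(records),
        n_events=int(events.sum()),
    )


def logrank_test(records: Sequence[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p value)."""
    groups = {r.group for r in records}
    if None in groups:
        raise ValueError("all records need a group for the log-rank test")
    if len(groups) != 2:
        raise ValueError(f"log-rank test requires exactly 2 non-empty groups, got {len(groups)}")
    g1, g2 = sorted(groups, key=lambda g: g.value)
    r1 = [r for r in records if r.group is g1]
    r2 = [r for r in records if r.group is g2]
    res = _ll_logrank(
        [r.time_months for r in r1],
        [r.time_months for r in r2],
        event_observed_A=[r.event for r in r1],
        event_observed_B=[r.event for r in r2],
    )
    return float(res.test_statistic), float(res.p_value)


def read_records(path: str | Path) -> list[SurvivalRecord]:
    """Read a TSV with columns ``patient_id, time_months, event, group``."""
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "time_months", "event", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing column(s): {', '.join(sorted(missing))}")
    return [
        SurvivalRecord(
            patient_id=str(row.patient_id),
            time_months=float(row.time_months),
            event=bool(int(row.event)),
            group=Group(row.group),
        )
        for row in df.itertuples()
    ]
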