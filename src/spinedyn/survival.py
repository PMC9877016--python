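"""Spine-survival cohorts, Kaplan-Meier estimation and the log-rank test.

A cohort is defined either as the spines *gained* between two observed
sessions or as all spines *present at* one session.  Because absence can
only be detected at an imaging session, the survival time axis is the
session index after cohort entry on the *scheduled* session axis (1 = the
first scheduled session after entry), not calendar days; indexing
scheduled rather than ROI-observed sessions keeps ROIs with occasional
missed sessions aligned on a common clock.  A spine's event is its first
observed absence; a spine
still present at its ROI's last observed session is right-censored there.
Spines that reappear after their first absence still count as events at
that first absence (reappearances are logged).

The product-limit estimator and the Mantel-Cox (log-rank) statistic are
implemented directly on these discrete session times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import ABSENT, PRESENT, ROITimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "CohortDef",
    "gained_between",
    "present_at",
    "SurvivalCohort",
    "SurvivalCurve",
    "LogRankResult",
    "build_cohort",
    "km_estimate",
    "logrank_test",
]


@dataclass(frozen=True)
class CohortDef:
    """Which spines enter a survival cohort.

    ``gained_between(d_a, d_b)``: spines absent at ``d_a`` and present at
    ``d_b`` (entry at ``d_b``).  ``present_at(d)``: spines present at ``d``
    (entry at ``d``).
    """

    kind: str  # "gained_between" | "present_at"
    days: tuple[int, ...]
    label: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "gained_between":
            if len(self.days) != 2 or self.days[0] >= self.days[1]:
                raise ValueError("gained_between needs two increasing days")
        elif self.kind == "present_at":
            if len(self.days) != 1:
                raise ValueError("present_at needs exactly one day")
        else:
            raise ValueError(f"unknown cohort kind {self.kind!r}")

    @property
    def entry_day(self) -> int:
        return self.days[-1]

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        return f"{self.kind}({','.join(str(d) for d in self.days)})"

    @classmethod
    def parse(cls, text: str) -> "CohortDef":
        """Parse compact syntax: ``gained:7:10`` or ``present:10``."""
        parts = str(text).split(":")
        kind = parts[0].strip().lower()
        days = tuple(int(p) for p in parts[1:])
        if kind in ("gained", "gained_between"):
            return cls("gained_between", days)
        if kind in ("present", "present_at"):
            return cls("present_at", days)
        raise ValueError(f"cannot parse cohort definition {text!r}")


def gained_between(d_a: int, d_b: int, label: str | None = None) -> CohortDef:
    return CohortDef("gained_between", (int(d_a), int(d_b)), label)


def present_at(d: int, label: str | None = None) -> CohortDef:
    return CohortDef("present_at", (int(d),), label)


@dataclass
class SurvivalCohort:
    """Per-spine follow-up of one cohort, pooled across ROIs.

    ``members`` columns: spine_id, roi_id, entry_day, time (sessions after
    entry to event or censoring, >= 1), event_observed, end_day (calendar
    day of the event or censoring session).
    """

    cohort_def: CohortDef
    members: pd.DataFrame
    excluded_rois: list[str] = field(default_factory=list)
    n_reappearances: int = 0

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def n_events(self) -> int:
        return int(self.members["event_observed"].sum())


def build_cohort(
    series: Iterable[ROITimeSeries], cohort_def: CohortDef
) -> SurvivalCohort:
    """Assemble a survival cohort across ROIs.

    ROIs not imaged at the cohort-defining day(s), or with no follow-up
    session after entry, are excluded with a warning; an error is raised
    only if *no* ROI qualifies.
    """
    rows = []
    excluded: list[str] = []
    reappear = 0
    n_series = 0
    for s in series:
        n_series += 1
        if any(d not in s.observed_days for d in cohort_def.days):
            excluded.append(s.roi_id)
            logger.warning(
                "cohort %s: ROI %r not imaged at the defining day(s); excluded",
                cohort_def.name,
                s.roi_id,
            )
            continue
        entry = cohort_def.entry_day
        followup = [d for d in s.observed_days if d > entry]
        if not followup:
            excluded.append(s.roi_id)
            logger.warning(
                "cohort %s: ROI %r has no session after entry day %d; excluded",
                cohort_def.name,
                s.roi_id,
                entry,
            )
            continue
        if cohort_def.kind == "gained_between":
            d_a, d_b = cohort_def.days
            member_mask = (~s.present_mask(d_a)) & s.present_mask(d_b)
        else:
            member_mask = s.present_mask(cohort_def.days[0])
        cols = [s.schedule.index(d) for d in followup]
        sub = s.presence[member_mask][:, cols]
        ids = np.asarray(s.spine_ids, dtype=object)[member_mask]
        absent = sub == ABSENT
        has_event = absent.any(axis=1)
        first_absent = np.where(has_event, absent.argmax(axis=1), len(cols) - 1)
        reappear += int(
            ((sub == PRESENT) & (np.cumsum(absent, axis=1) > 0)).any(axis=1).sum()
        )
        entry_pos = s.schedule.index(entry)
        for sid, ev, idx in zip(ids, has_event, first_absent):
            end_day = followup[int(idx)]
            rows.append(
                (
                    str(sid),
                    s.roi_id,
                    entry,
                    s.schedule.index(end_day) - entry_pos,
                    bool(ev),
                    end_day,
                )
            )
    if n_series and len(excluded) == n_series:
        raise ValueError(
            f"cohort {cohort_def.name}: no ROI observed at the defining days"
        )
    if reappear:
        logger.info(
            "cohort %s: %d spine(s) reappeared after their first absence "
            "(still counted as events at first absence)",
            cohort_def.name,
            reappear,
        )
    members = pd.DataFrame(
        rows,
        columns=[
            "spine_id",
            "roi_id",
            "entry_day",
            "time",
            "event_observed",
            "end_day",
        ],
    )
    return SurvivalCohort(cohort_def, members, excluded, reappear)


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate on the session axis.

    ``table`` columns: time (sessions after entry; includes 0), at_risk,
    events, censored, survival.
    """

    cohort_name: str
    table: pd.DataFrame

    def survival_at(self, time: int) -> float:
        t = self.table
        eligible = t[t["time"] <= time]
        return float(eligible["survival"].iloc[-1])


def km_estimate(cohort: SurvivalCohort) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod (1 - d_j / n_j)."""
    if cohort.n == 0:
        raise ValueError(f"cohort {cohort.cohort_def.name} is empty")
    times = cohort.members["time"].to_numpy()
    events = cohort.members["event_observed"].to_numpy(dtype=bool)
    grid = np.unique(times)
    rows = [(0, int(len(times)), 0, 0, 1.0)]
    s = 1.0
    for t in grid:
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        c = int(((times == t) & ~events).sum())
        if d:
            s *= 1.0 - d / n_at_risk
        rows.append((int(t), n_at_risk, d, c, s))
    table = pd.DataFrame(
        rows, columns=["time", "at_risk", "events", "censored", "survival"]
    )
    return SurvivalCurve(cohort.cohort_def.name, table)


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    df: int = 1


def logrank_test(a: SurvivalCohort, b: SurvivalCohort) -> LogRankResult:
    """Two-group Mantel-Cox log-rank test.

    Sums observed-minus-expected events for group ``a`` over the pooled
    event times, with the hypergeometric variance at each time; the squared
    standardized sum is referred to chi-square with 1 df (two-sided).
    """
    for c in (a, b):
        if c.n == 0:
            raise ValueError(f"cohort {c.cohort_def.name} has no at-risk members")
    t_a = a.members["time"].to_numpy()
    e_a = a.members["event_observed"].to_numpy(dtype=bool)
    t_b = b.members["time"].to_numpy()
    e_b = b.members["event_observed"].to_numpy(dtype=bool)
    event_times = np.unique(np.concatenate([t_a[e_a], t_b[e_b]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = int((t_a >= t).sum())
        n2 = int((t_b >= t).sum())
        d1 = int(((t_a == t) & e_a).sum())
        d2 = int(((t_b == t) & e_b).sum())
        n = n1 + n2
        d = d1 + d2
        if n <= 1:
            continue
        expected1 = d * n1 / n
        o_minus_e += d1 - expected1
        var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        # no informative event time (e.g. no events at all): no evidence
        return LogRankResult(0.0, 1.0, a.n, b.n)
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(float(chi2), p, a.n, b.n)
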