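"""Spine-fate classification and per-ROI dynamics metrics.

Between two consecutive observed sessions every spine is *stable* (present
at both), *gained* (present only at the later) or *lost* (present only at
the earlier session); a spine gained in one interval and lost in the next
is *transient*.  From these partitions the module computes, per ROI:

* turnover ratio — (gained + lost) / (spines present at both sessions
  combined),
* gained / lost / stable fractions — relative to the spine count at the
  earlier session (the stable and lost fractions are complementary),
* transient fraction — relative to the spine count at the middle session,
* spine density — present spines per µm of measured dendrite, optionally
  normalized to the ROI's mean baseline density.

Group-level summaries weight each ROI equally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .annotations import ROITimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "IntervalEvents",
    "FateFractions",
    "classify_interval",
    "turnover_ratio",
    "fate_fractions",
    "transient_fraction",
    "spine_density",
    "density_table",
    "normalize_density",
    "dynamics_table",
    "group_summary",
]

GainedDenominator = Literal["n_prev", "n_next"]


@dataclass(frozen=True)
class IntervalEvents:
    """The stable/gained/lost partition for one consecutive-session pair."""

    roi_id: str
    day_pair: tuple[int, int]
    stable_ids: frozenset[str]
    gained_ids: frozenset[str]
    lost_ids: frozenset[str]

    @property
    def n_prev(self) -> int:
        return len(self.stable_ids) + len(self.lost_ids)

    @property
    def n_next(self) -> int:
        return len(self.stable_ids) + len(self.gained_ids)


@dataclass(frozen=True)
class FateFractions:
    gained: float
    lost: float
    stable: float


def _check_consecutive(series: ROITimeSeries, t_i: int, t_next: int) -> None:
    obs = series.observed_days
    if t_i not in obs or t_next not in obs:
        raise ValueError(
            f"ROI {series.roi_id!r}: days ({t_i}, {t_next}) must both be "
            f"observed sessions (observed: {obs})"
        )
    if obs.index(t_next) != obs.index(t_i) + 1:
        raise ValueError(
            f"ROI {series.roi_id!r}: days ({t_i}, {t_next}) are not "
            "consecutive observed sessions"
        )


def classify_interval(
    series: ROITimeSeries, t_i: int, t_next: int
) -> IntervalEvents:
    """Partition spines into stable / gained / lost between two
    consecutive observed sessions of this ROI."""
    _check_consecutive(series, t_i, t_next)
    prev_mask = series.present_mask(t_i)
    next_mask = series.present_mask(t_next)
    ids = np.asarray(series.spine_ids, dtype=object)
    return IntervalEvents(
        roi_id=series.roi_id,
        day_pair=(int(t_i), int(t_next)),
        stable_ids=frozenset(ids[prev_mask & next_mask]),
        gained_ids=frozenset(ids[~prev_mask & next_mask]),
        lost_ids=frozenset(ids[prev_mask & ~next_mask]),
    )


def turnover_ratio(ev: IntervalEvents) -> float:
    """(gained + lost) / (total spines present at both sessions combined).

    Undefined (NaN) when no spine is present at either session.
    """
    total = ev.n_prev + ev.n_next
    if total == 0:
        return float("nan")
    return (len(ev.gained_ids) + len(ev.lost_ids)) / total


def fate_fractions(
    ev: IntervalEvents,
    gained_denominator: GainedDenominator = "n_prev",
) -> FateFractions:
    """Gained / lost / stable fractions for one interval.

    Lost and stable fractions are always relative to the spine count at the
    earlier session, so they sum to 1.  The gained fraction uses the same
    denominator by default; ``gained_denominator="n_next"`` divides by the
    later session's count instead.
    """
    if ev.n_prev == 0:
        nan = float("nan")
        return FateFractions(nan, nan, nan)
    lost = len(ev.lost_ids) / ev.n_prev
    stable = len(ev.stable_ids) / ev.n_prev
    if gained_denominator == "n_prev":
        gained = len(ev.gained_ids) / ev.n_prev
    elif gained_denominator == "n_next":
        gained = len(ev.gained_ids) / ev.n_next if ev.n_next else float("nan")
    else:
        raise ValueError(f"unknown gained denominator {gained_denominator!r}")
    return FateFractions(gained=gained, lost=lost, stable=stable)


def transient_fraction(
    series: ROITimeSeries, t_prev: int, t_i: int, t_next: int
) -> float:
    """Fraction of spines at the middle session that were gained in the
    first interval and lost again in the second.

    Requires three consecutive observed sessions; NaN when no spine is
    present at the middle session.
    """
    first = classify_interval(series, t_prev, t_i)
    second = classify_interval(series, t_i, t_next)
    n_mid = series.n_present(t_i)
    if n_mid == 0:
        return float("nan")
    return len(first.gained_ids & second.lost_ids) / n_mid


def spine_density(series: ROITimeSeries, t: int) -> float:
    """Present spines per µm of measured dendrite at an observed session."""
    total = series.total_dendrite_length_um
    if total <= 0:
        raise ValueError(f"ROI {series.roi_id!r}: no measured dendrite length")
    return series.n_present(t) / total


def density_table(series: Iterable[ROITimeSeries]) -> pd.DataFrame:
    """Per-ROI, per-observed-session spine densities (long format)."""
    rows = []
    for s in series:
        for d in s.observed_days:
            rows.append(
                (s.mouse_id, s.roi_id, s.age, s.treatment, d, spine_density(s, d))
            )
    return pd.DataFrame(
        rows,
        columns=["mouse_id", "roi_id", "age", "treatment", "session_day", "density"],
    )


def normalize_density(
    density: pd.DataFrame, baseline_days: Sequence[int]
) -> pd.DataFrame:
    """Add ``normalized_density`` = density / ROI mean baseline density.

    ROIs without an observed baseline session of positive density are
    excluded from the result, with a warning.
    """
    baseline_days = set(int(d) for d in baseline_days)
    out = []
    for roi_id, g in density.groupby("roi_id", sort=True):
        base = g.loc[g["session_day"].isin(baseline_days), "density"]
        if len(base) == 0 or base.mean() <= 0:
            logger.warning(
                "normalize_density: ROI %r has no usable baseline session; "
                "excluded",
                roi_id,
            )
            continue
        g = g.copy()
        g["normalized_density"] = g["density"] / base.mean()
        out.append(g)
    if not out:
        return density.iloc[0:0].assign(normalized_density=pd.Series(dtype=float))
    return pd.concat(out, ignore_index=True)


def _roi_dynamics_rows(
    series: ROITimeSeries, gained_denominator: GainedDenominator
) -> list[dict]:
    rows = []
    pairs = series.consecutive_observed_pairs()
    events = [classify_interval(series, a, b) for a, b in pairs]
    for k, (ev, (a, b)) in enumerate(zip(events, pairs)):
        fr = fate_fractions(ev, gained_denominator)
        # the transient fraction at the middle day b needs the next interval
        if k + 1 < len(pairs):
            transient = transient_fraction(series, a, b, pairs[k + 1][1])
        else:
            transient = float("nan")
        rows.append(
            {
                "mouse_id": series.mouse_id,
                "roi_id": series.roi_id,
                "age": series.age,
                "treatment": series.treatment,
                "day_prev": a,
                "day": b,
                "interval_days": b - a,
                "n_prev": ev.n_prev,
                "n_next": ev.n_next,
                "n_gained": len(ev.gained_ids),
                "n_lost": len(ev.lost_ids),
                "n_stable": len(ev.stable_ids),
                "turnover_ratio": turnover_ratio(ev),
                "frac_gained": fr.gained,
                "frac_lost": fr.lost,
                "frac_stable": fr.stable,
                "frac_transient": transient,
            }
        )
    return rows


DYNAMICS_METRICS = (
    "turnover_ratio",
    "frac_gained",
    "frac_lost",
    "frac_stable",
    "frac_transient",
)


def dynamics_table(
    series: Iterable[ROITimeSeries],
    baseline_days: Sequence[int] | None = None,
    gained_denominator: GainedDenominator = "n_prev",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Compute the tidy dynamics outputs for a dataset.

    Returns ``(dynamics_long, density_long, summary)``: one row per
    ROI x interval (metrics attributed to the later day of the pair), one
    row per ROI x session (density and baseline-normalized density), and a
    group mean +/- SEM per session/interval with each ROI weighted equally.
    """
    series = list(series)
    if baseline_days is None:
        if not series:
            raise ValueError("empty dataset")
        baseline_days = series[0].schedule.baseline_days
    dyn_rows: list[dict] = []
    for s in series:
        dyn_rows.extend(_roi_dynamics_rows(s, gained_denominator))
    dynamics_long = pd.DataFrame(dyn_rows)
    density_long = normalize_density(density_table(series), baseline_days)
    summary = group_summary(dynamics_long, density_long)
    return dynamics_long, density_long, summary


def group_summary(
    dynamics_long: pd.DataFrame, density_long: pd.DataFrame
) -> pd.DataFrame:
    """Group mean +/- SEM per session day for every metric (one ROI = one
    data point)."""
    pieces = []
    if len(dynamics_long):
        melted = dynamics_long.melt(
            id_vars=["age", "treatment", "day"],
            value_vars=list(DYNAMICS_METRICS),
            var_name="metric",
        )
        pieces.append(melted)
    if len(density_long):
        value_vars = [
            c for c in ("density", "normalized_density") if c in density_long
        ]
        melted = density_long.rename(columns={"session_day": "day"}).melt(
            id_vars=["age", "treatment", "day"],
            value_vars=value_vars,
            var_name="metric",
        )
        pieces.append(melted)
    if not pieces:
        return pd.DataFrame(
            columns=["age", "treatment", "day", "metric", "mean", "sem", "n"]
        )
    longf = pd.concat(pieces, ignore_index=True).dropna(subset=["value"])
    out = (
        longf.groupby(["age", "treatment", "day", "metric"], sort=True)["value"]
        .agg(mean="mean", sem="sem", n="count")
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
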