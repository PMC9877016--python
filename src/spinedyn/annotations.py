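"""Annotation data model and long-format I/O for chronic spine-imaging studies.

The unit of analysis is a protrusion (dendritic spine) tracked across imaging
sessions within a region of interest (ROI).  Data arrive as long-format CSV
tables: one row per spine per imaged session, carrying a present/absent flag
and, where the spine is present, the annotated protrusion length in µm.

Sessions an ROI was never imaged at are first-class missing data
(``NOT_IMAGED``), distinct from an imaged session at which a spine was absent
(``ABSENT``).  All downstream dynamics and survival computations operate on
*observed* sessions only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ABSENT",
    "PRESENT",
    "NOT_IMAGED",
    "DEFAULT_SESSION_DAYS",
    "DEFAULT_TREATMENT_WINDOW",
    "DEFAULT_MIN_LENGTH_UM",
    "ImagingSchedule",
    "SpineTrack",
    "ROITimeSeries",
    "Violation",
    "ValidationReport",
    "SchemaError",
    "read_annotations",
    "write_annotations",
    "filter_protrusions",
    "validate",
    "write_table",
    "read_table",
]

# Presence codes stored in the per-ROI (spine x session) matrix.
ABSENT: int = 0
PRESENT: int = 1
NOT_IMAGED: int = 2

#: Protrusions must be strictly longer than this to count as spines (µm).
DEFAULT_MIN_LENGTH_UM: float = 0.4

#: Default imaging schedule, in days relative to treatment start: three
#: baseline sessions, eight sessions during the 28-day treatment, four
#: post-treatment sessions (15 sessions total).  Always configurable.
DEFAULT_SESSION_DAYS: tuple[int, ...] = (
    -7, -4, -1, 4, 7, 10, 13, 16, 19, 22, 25, 35, 42, 49, 56,
)
DEFAULT_TREATMENT_WINDOW: tuple[int, int] = (0, 28)

CSV_COLUMNS = [
    "mouse_id",
    "roi_id",
    "group_age",
    "group_treatment",
    "segment_id",
    "segment_length_um",
    "spine_id",
    "session_day",
    "present",
    "length_um",
]

_AGES = ("young", "old")
_TREATMENTS = ("vehicle", "THC")


class SchemaError(ValueError):
    """Raised when an annotation table violates the documented schema."""


def _normalize_age(value: str) -> str:
    v = str(value).strip().lower()
    if v not in _AGES:
        raise SchemaError(f"unknown age group {value!r}; expected one of {_AGES}")
    return v


def _normalize_treatment(value: str) -> str:
    v = str(value).strip().lower()
    if v == "thc":
        return "THC"
    if v == "vehicle":
        return "vehicle"
    raise SchemaError(
        f"unknown treatment {value!r}; expected one of {_TREATMENTS}"
    )


@dataclass(frozen=True)
class ImagingSchedule:
    """The planned imaging time axis of a study.

    Parameters
    ----------
    session_days
        Strictly increasing integer day labels relative to treatment start
        (treatment start = day 0).
    treatment_window
        ``(start_day, end_day)`` of the treatment period.
    """

    session_days: tuple[int, ...] = DEFAULT_SESSION_DAYS
    treatment_window: tuple[int, int] = DEFAULT_TREATMENT_WINDOW

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.session_days)
        object.__setattr__(self, "session_days", days)
        window = (int(self.treatment_window[0]), int(self.treatment_window[1]))
        object.__setattr__(self, "treatment_window", window)
        if len(days) < 2:
            raise ValueError("schedule needs at least 2 sessions")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("session_days must be strictly increasing")
        if window[0] >= window[1]:
            raise ValueError("treatment_window start must precede end")

    @property
    def n_sessions(self) -> int:
        return len(self.session_days)

    @property
    def baseline_days(self) -> tuple[int, ...]:
        """Sessions before treatment start."""
        return tuple(d for d in self.session_days if d < self.treatment_window[0])

    def index(self, day: int) -> int:
        try:
            return self.session_days.index(int(day))
        except ValueError:
            raise KeyError(f"day {day} is not in the imaging schedule") from None

    def __contains__(self, day: int) -> bool:
        return int(day) in self.session_days


@dataclass
class SpineTrack:
    """One protrusion's identity and per-session state.

    ``presence`` maps every scheduled session day to one of the codes
    ``PRESENT`` / ``ABSENT`` / ``NOT_IMAGED``; ``length_um`` holds the
    annotated protrusion length where one was recorded.
    """

    spine_id: str
    segment_id: str
    presence: dict[int, int]
    length_um: dict[int, float] = field(default_factory=dict)

    def present_days(self) -> list[int]:
        return [d for d, p in self.presence.items() if p == PRESENT]


class ROITimeSeries:
    """All spine tracks of one ROI, with dendrite lengths and schedule.

    Internally presence is a dense ``(n_spines, n_sessions)`` int8 matrix
    over the full schedule; columns of sessions the ROI was not imaged at
    are uniformly ``NOT_IMAGED``.
    """

    def __init__(
        self,
        roi_id: str,
        mouse_id: str,
        age: str,
        treatment: str,
        schedule: ImagingSchedule,
        spine_ids: Sequence[str],
        segment_ids: Sequence[str],
        presence: np.ndarray,
        lengths: np.ndarray | None,
        segment_lengths_um: dict[str, float],
        observed_days: Sequence[int],
    ) -> None:
        self.roi_id = str(roi_id)
        self.mouse_id = str(mouse_id)
        self.age = _normalize_age(age)
        self.treatment = _normalize_treatment(treatment)
        self.schedule = schedule
        self.spine_ids = [str(s) for s in spine_ids]
        self.segment_ids = [str(s) for s in segment_ids]
        n, m = len(self.spine_ids), schedule.n_sessions
        presence = np.asarray(presence, dtype=np.int8)
        if presence.shape != (n, m):
            raise ValueError(
                f"presence matrix shape {presence.shape} != ({n}, {m})"
            )
        if lengths is None:
            lengths = np.full((n, m), np.nan)
        lengths = np.asarray(lengths, dtype=float)
        if lengths.shape != (n, m):
            raise ValueError(f"lengths matrix shape {lengths.shape} != ({n}, {m})")
        self.presence = presence
        self.lengths = lengths
        self.segment_lengths_um = {
            str(k): float(v) for k, v in segment_lengths_um.items()
        }
        for seg, length in self.segment_lengths_um.items():
            if length <= 0:
                raise ValueError(
                    f"segment {seg!r} in ROI {roi_id!r} has non-positive "
                    f"length {length}"
                )
        self.observed_days = tuple(sorted(int(d) for d in observed_days))
        for d in self.observed_days:
            if d not in schedule:
                raise SchemaError(
                    f"observed day {d} of ROI {roi_id!r} is not in the schedule"
                )
        # enforce the invariant: unobserved columns are uniformly NOT_IMAGED
        observed_idx = [schedule.index(d) for d in self.observed_days]
        mask = np.ones(m, dtype=bool)
        mask[observed_idx] = False
        self.presence[:, mask] = NOT_IMAGED

    # -- structure -----------------------------------------------------

    @property
    def group(self) -> tuple[str, str]:
        return (self.age, self.treatment)

    @property
    def n_spines(self) -> int:
        return len(self.spine_ids)

    @property
    def total_dendrite_length_um(self) -> float:
        return float(sum(self.segment_lengths_um.values()))

    def _col(self, day: int) -> int:
        if int(day) not in self.observed_days:
            raise KeyError(
                f"day {day} was not imaged for ROI {self.roi_id!r}"
            )
        return self.schedule.index(day)

    def present_mask(self, day: int) -> np.ndarray:
        """Boolean mask over spines present at an observed session."""
        return self.presence[:, self._col(day)] == PRESENT

    def present_ids(self, day: int) -> set[str]:
        mask = self.present_mask(day)
        return {sid for sid, m in zip(self.spine_ids, mask) if m}

    def n_present(self, day: int) -> int:
        return int(self.present_mask(day).sum())

    def consecutive_observed_pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.observed_days, self.observed_days[1:]))

    @property
    def tracks(self) -> list[SpineTrack]:
        """Materialize per-spine track views (convenience accessor)."""
        days = self.schedule.session_days
        out = []
        for i, sid in enumerate(self.spine_ids):
            presence = {d: int(self.presence[i, j]) for j, d in enumerate(days)}
            length = {
                d: float(self.lengths[i, j])
                for j, d in enumerate(days)
                if np.isfinite(self.lengths[i, j])
            }
            out.append(SpineTrack(sid, self.segment_ids[i], presence, length))
        return out

    @classmethod
    def from_tracks(
        cls,
        roi_id: str,
        mouse_id: str,
        age: str,
        treatment: str,
        schedule: ImagingSchedule,
        tracks: Iterable[SpineTrack],
        segment_lengths_um: dict[str, float],
        observed_days: Sequence[int],
    ) -> "ROITimeSeries":
        tracks = list(tracks)
        n, m = len(tracks), schedule.n_sessions
        presence = np.full((n, m), NOT_IMAGED, dtype=np.int8)
        lengths = np.full((n, m), np.nan)
        observed = set(int(d) for d in observed_days)
        for i, tr in enumerate(tracks):
            for d in observed:
                presence[i, schedule.index(d)] = ABSENT
            for d, p in tr.presence.items():
                if d not in schedule:
                    raise SchemaError(
                        f"track {tr.spine_id!r} references day {d} outside "
                        "the schedule"
                    )
                if d in observed:
                    presence[i, schedule.index(d)] = p
            for d, v in tr.length_um.items():
                lengths[i, schedule.index(d)] = v
        return cls(
            roi_id,
            mouse_id,
            age,
            treatment,
            schedule,
            [t.spine_id for t in tracks],
            [t.segment_id for t in tracks],
            presence,
            lengths,
            segment_lengths_um,
            sorted(observed),
        )

    # -- equality (used by round-trip tests) ---------------------------

    def equals(self, other: "ROITimeSeries") -> bool:
        if not isinstance(other, ROITimeSeries):
            return False
        if (
            self.roi_id != other.roi_id
            or self.mouse_id != other.mouse_id
            or self.group != other.group
            or self.schedule != other.schedule
            or self.observed_days != other.observed_days
            or self.segment_lengths_um != other.segment_lengths_um
        ):
            return False
        order_a = np.argsort(self.spine_ids, kind="stable")
        order_b = np.argsort(other.spine_ids, kind="stable")
        if [self.spine_ids[i] for i in order_a] != [
            other.spine_ids[i] for i in order_b
        ]:
            return False
        if [self.segment_ids[i] for i in order_a] != [
            other.segment_ids[i] for i in order_b
        ]:
            return False
        if not np.array_equal(self.presence[order_a], other.presence[order_b]):
            return False
        la, lb = self.lengths[order_a], other.lengths[order_b]
        both = np.isfinite(la) & np.isfinite(lb)
        if not np.array_equal(np.isfinite(la), np.isfinite(lb)):
            return False
        return bool(np.allclose(la[both], lb[both]))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ROITimeSeries {self.roi_id!r} ({self.age}/{self.treatment}): "
            f"{self.n_spines} spines, {len(self.observed_days)} sessions>"
        )


# ----------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    roi_id: str
    code: str
    message: str


@dataclass
class ValidationReport:
    """Schema-violation listing; an empty report means the dataset passes."""

    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(v.roi_id, v.code, v.message) for v in self.violations],
            columns=["roi_id", "code", "message"],
        )


def validate(
    series: Iterable[ROITimeSeries],
    min_length_um: float = DEFAULT_MIN_LENGTH_UM,
) -> ValidationReport:
    """Check a dataset against the annotation schema.

    Violations are report entries, never exceptions: duplicate spine ids
    within an ROI, presence recorded on an unobserved session, a present
    spine on a segment without a recorded length, retained sub-threshold
    protrusions, and negative protrusion lengths.
    """
    report = ValidationReport()
    seen_rois: set[tuple[str, str]] = set()
    for s in series:
        key = (s.mouse_id, s.roi_id)
        if key in seen_rois:
            report.violations.append(
                Violation(s.roi_id, "duplicate_roi", f"ROI {key} appears twice")
            )
        seen_rois.add(key)
        counts = pd.Series(s.spine_ids).value_counts()
        for sid, c in counts[counts > 1].items():
            report.violations.append(
                Violation(
                    s.roi_id,
                    "duplicate_spine_id",
                    f"spine id {sid!r} appears {c} times",
                )
            )
        observed_idx = {s.schedule.index(d) for d in s.observed_days}
        days = s.schedule.session_days
        for i, sid in enumerate(s.spine_ids):
            for j, d in enumerate(days):
                code = int(s.presence[i, j])
                if j not in observed_idx and code != NOT_IMAGED:
                    report.violations.append(
                        Violation(
                            s.roi_id,
                            "presence_on_unobserved_session",
                            f"spine {sid!r} has state {code} at unimaged day {d}",
                        )
                    )
                if code == PRESENT:
                    seg = s.segment_ids[i]
                    if seg not in s.segment_lengths_um:
                        report.violations.append(
                            Violation(
                                s.roi_id,
                                "missing_segment_length",
                                f"spine {sid!r} present on segment {seg!r} "
                                "with no recorded length",
                            )
                        )
                    length = s.lengths[i, j]
                    if np.isfinite(length):
                        if length < 0:
                            report.violations.append(
                                Violation(
                                    s.roi_id,
                                    "negative_length",
                                    f"spine {sid!r} day {d}: length {length}",
                                )
                            )
                        elif length <= min_length_um:
                            report.violations.append(
                                Violation(
                                    s.roi_id,
                                    "subthreshold_protrusion_retained",
                                    f"spine {sid!r} day {d}: length "
                                    f"{length} µm <= {min_length_um} µm",
                                )
                            )
    return report


# ----------------------------------------------------------------------
# reading and writing


def read_annotations(
    path: str | Path, schedule: ImagingSchedule
) -> list[ROITimeSeries]:
    """Read a long-format annotation CSV into per-ROI time series.

    One row = one spine at one imaged session.  An ROI-session is *observed*
    iff at least one row mentions it; spines of an observed ROI-session with
    no row are completed as absent; ROI-sessions never mentioned are
    ``NOT_IMAGED`` for every track.
    """
    df = pd.read_csv(
        path,
        dtype={"present": "Int64", "session_day": "Int64"},
        float_precision="round_trip",
    )
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    out: list[ROITimeSeries] = []
    # row numbers refer to the CSV file (1 header line + 1-based data rows)
    df = df.reset_index(drop=True)
    df["_row"] = df.index + 2

    for bad in df.index[df["present"].isna() | ~df["present"].isin([0, 1])]:
        raise SchemaError(
            f"{path}: row {df.at[bad, '_row']}: present flag must be 0 or 1"
        )
    for bad in df.index[df["session_day"].isna()]:
        raise SchemaError(
            f"{path}: row {df.at[bad, '_row']}: missing/invalid session_day"
        )
    unknown = sorted(
        set(int(d) for d in df["session_day"].unique())
        - set(schedule.session_days)
    )
    if unknown:
        raise SchemaError(
            f"{path}: session day(s) {unknown} are not in the imaging schedule"
        )
    neg = df.index[df["length_um"].notna() & (df["length_um"] < 0)]
    if len(neg):
        raise SchemaError(
            f"{path}: row {df.at[neg[0], '_row']}: negative protrusion length"
        )

    for (mouse_id, roi_id), g in df.groupby(["mouse_id", "roi_id"], sort=True):
        ages = g["group_age"].unique()
        treatments = g["group_treatment"].unique()
        if len(ages) > 1 or len(treatments) > 1:
            raise SchemaError(
                f"{path}: ROI {roi_id!r} has inconsistent group labels"
            )
        dup = g.duplicated(subset=["spine_id", "session_day"], keep=False)
        if dup.any():
            conflict = (
                g[dup]
                .groupby(["spine_id", "session_day"])[["present", "length_um"]]
                .nunique()
            )
            if (conflict > 1).any(axis=None):
                row = int(g[dup]["_row"].iloc[0])
                raise SchemaError(
                    f"{path}: row {row}: conflicting duplicate rows for a "
                    "spine-session"
                )
            g = g.drop_duplicates(subset=["spine_id", "session_day"], keep="last")
        observed_days = sorted(int(d) for d in g["session_day"].unique())
        spine_ids = list(pd.unique(g["spine_id"].astype(str)))
        sindex = {sid: i for i, sid in enumerate(spine_ids)}
        n, m = len(spine_ids), schedule.n_sessions
        presence = np.full((n, m), NOT_IMAGED, dtype=np.int8)
        lengths = np.full((n, m), np.nan)
        for d in observed_days:
            presence[:, schedule.index(d)] = ABSENT
        segment_of: dict[str, str] = {}
        segment_lengths: dict[str, float] = {}
        for row in g.itertuples(index=False):
            i = sindex[str(row.spine_id)]
            j = schedule.index(int(row.session_day))
            presence[i, j] = PRESENT if int(row.present) == 1 else ABSENT
            if pd.notna(row.length_um):
                lengths[i, j] = float(row.length_um)
            seg = str(row.segment_id)
            prev = segment_of.setdefault(str(row.spine_id), seg)
            if prev != seg:
                raise SchemaError(
                    f"{path}: row {row._row}: spine {row.spine_id!r} changes "
                    f"segment ({prev!r} -> {seg!r})"
                )
            if pd.notna(row.segment_length_um):
                segment_lengths[seg] = float(row.segment_length_um)
        out.append(
            ROITimeSeries(
                roi_id=str(roi_id),
                mouse_id=str(mouse_id),
                age=str(ages[0]),
                treatment=str(treatments[0]),
                schedule=schedule,
                spine_ids=spine_ids,
                segment_ids=[segment_of[s] for s in spine_ids],
                presence=presence,
                lengths=lengths,
                segment_lengths_um=segment_lengths,
                observed_days=observed_days,
            )
        )
    return out


def write_annotations(
    series: Iterable[ROITimeSeries], path: str | Path
) -> pd.DataFrame:
    """Write ROI time series back to the long-format CSV schema.

    Emits one row per track per observed session (explicit absences
    included), so presence-record counts are conserved through a
    write/read round-trip.
    """
    rows = []
    for s in series:
        for i, sid in enumerate(s.spine_ids):
            seg = s.segment_ids[i]
            seg_len = s.segment_lengths_um.get(seg, np.nan)
            for d in s.observed_days:
                j = s.schedule.index(d)
                length = s.lengths[i, j]
                rows.append(
                    (
                        s.mouse_id,
                        s.roi_id,
                        s.age,
                        s.treatment,
                        seg,
                        seg_len,
                        sid,
                        d,
                        int(s.presence[i, j] == PRESENT),
                        length if np.isfinite(length) else np.nan,
                    )
                )
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    # annotation tables must round-trip losslessly
    write_table(df, path, float_format=None)
    return df


def filter_protrusions(
    series: ROITimeSeries,
    min_length_um: float = DEFAULT_MIN_LENGTH_UM,
    mode: Literal["per_session", "per_track"] = "per_session",
) -> ROITimeSeries:
    """Apply the minimum-protrusion-length rule (strictly longer than).

    ``per_session`` (default) re-evaluates the rule at every session: any
    presence record with recorded length <= ``min_length_um`` becomes an
    absence.  ``per_track`` evaluates it once, at the track's first
    presence, and drops the whole track if that first protrusion fails.
    Tracks with no remaining presence are dropped.  Decisions are logged.
    """
    if np.nanmin(series.lengths, initial=np.inf) < 0:
        raise ValueError(f"ROI {series.roi_id!r}: negative protrusion length")
    presence = series.presence.copy()
    lengths = series.lengths.copy()
    keep = np.ones(series.n_spines, dtype=bool)
    days = series.schedule.session_days

    if mode == "per_session":
        fails = (
            (presence == PRESENT)
            & np.isfinite(lengths)
            & (lengths <= min_length_um)
        )
        for i, j in zip(*np.nonzero(fails)):
            logger.debug(
                "filter: ROI %s spine %s day %s length %.3f µm <= %.3f -> absent",
                series.roi_id,
                series.spine_ids[i],
                days[j],
                lengths[i, j],
                min_length_um,
            )
        presence[fails] = ABSENT
    elif mode == "per_track":
        for i in range(series.n_spines):
            present_cols = np.nonzero(presence[i] == PRESENT)[0]
            if len(present_cols) == 0:
                continue
            first = present_cols[0]
            first_len = lengths[i, first]
            if np.isfinite(first_len) and first_len <= min_length_um:
                keep[i] = False
                logger.debug(
                    "filter: ROI %s spine %s dropped (first annotation "
                    "%.3f µm <= %.3f)",
                    series.roi_id,
                    series.spine_ids[i],
                    first_len,
                    min_length_um,
                )
    else:  # pragma: no cover - guarded by Literal typing
        raise ValueError(f"unknown filter mode {mode!r}")

    keep &= (presence == PRESENT).any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "filter: ROI %s dropped %d track(s) with no remaining presence",
            series.roi_id,
            n_dropped,
        )
    return ROITimeSeries(
        roi_id=series.roi_id,
        mouse_id=series.mouse_id,
        age=series.age,
        treatment=series.treatment,
        schedule=series.schedule,
        spine_ids=[s for s, k in zip(series.spine_ids, keep) if k],
        segment_ids=[s for s, k in zip(series.segment_ids, keep) if k],
        presence=presence[keep],
        lengths=lengths[keep],
        segment_lengths_um=series.segment_lengths_um,
        observed_days=series.observed_days,
    )


# ----------------------------------------------------------------------
# generic tidy-table round trip

_FLOAT_FORMAT = "%.10g"


def write_table(
    df: pd.DataFrame, path: str | Path, float_format: str | None = _FLOAT_FORMAT
) -> None:
    """Write a tidy result table as CSV with deterministic formatting.

    ``float_format=None`` uses the shortest exact decimal representation
    (lossless float round-trip).
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=float_format)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
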