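"""Synthetic chronic-imaging studies from a discrete-time birth-death model.

Each ROI carries a spine population observed only at scheduled imaging
sessions.  Between sessions, every spine survives each calendar day with a
class-specific probability (``nascent`` spines — formed within the last
``nascent_threshold`` intervals — are less stable than ``persistent``
ones), and new spines form as a Poisson process proportional to the ROI's
dendrite length.  Treatment effects are multiplicative modifiers on the
daily gain rate or on the daily loss probability of a stability class,
active inside a calendar-day window.  Because dynamics are compounded per
day, schedule gaps of unequal length (e.g. the 10-day gap after treatment
ends) behave consistently.

Survival probabilities in the configuration are referenced to a 3-day
interval (the modal spacing of the default schedule) and converted to
daily probabilities internally.

The module also provides a parameter-recovery harness
(:func:`recover_loss_modifier`) that estimates a loss-hazard multiplier
between two groups from the empirical per-interval loss of persistent
spines, with a bootstrap confidence interval over ROIs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from scipy import optimize

from .annotations import (
    DEFAULT_SESSION_DAYS,
    DEFAULT_TREATMENT_WINDOW,
    NOT_IMAGED,
    ImagingSchedule,
    ROITimeSeries,
    write_annotations,
)

__all__ = [
    "TreatmentModifier",
    "GroupParams",
    "SimulationConfig",
    "GROUPS",
    "group_key",
    "simulate_roi",
    "simulate_study",
    "write_study",
    "default_scenarios",
    "null_scenarios",
    "LossModifierResult",
    "recover_loss_modifier",
]

GROUPS: tuple[tuple[str, str], ...] = (
    ("young", "vehicle"),
    ("young", "THC"),
    ("old", "vehicle"),
    ("old", "THC"),
)

ModifierMetric = Literal["gain_rate", "loss_hazard_nascent", "loss_hazard_persistent"]


def group_key(age: str, treatment: str) -> str:
    return f"{age}_{treatment}"


class TreatmentModifier(BaseModel):
    """Multiplier on a daily rate, active for days inside ``window``."""

    metric: ModifierMetric
    multiplier: float = Field(gt=0)
    window: tuple[int, int]

    def active(self, day: int) -> bool:
        return self.window[0] <= day <= self.window[1]


class GroupParams(BaseModel):
    """Birth-death parameters of one age x treatment group."""

    n_mice: int = Field(gt=0)
    n_rois: int = Field(gt=0)
    n_segments: tuple[int, int] = (2, 4)
    #: mean and SD of one dendritic segment's measured length (µm)
    segment_length_um: tuple[float, float] = (40.0, 10.0)
    #: expected spines per µm at the first session
    baseline_density: float = Field(ge=0)
    #: new spines per µm per reference interval
    gain_rate: float = Field(ge=0)
    #: per-reference-interval survival probability of established spines
    survival_persistent: float = Field(ge=0, le=1)
    #: per-reference-interval survival probability of recently formed spines
    survival_nascent: float = Field(ge=0, le=1)
    #: intervals a spine stays nascent after formation
    nascent_threshold: int = Field(default=2, ge=0)
    modifiers: list[TreatmentModifier] = Field(default_factory=list)

    def loss_multiplier(self, day: int, nascent: bool) -> float:
        metric = "loss_hazard_nascent" if nascent else "loss_hazard_persistent"
        m = 1.0
        for mod in self.modifiers:
            if mod.metric == metric and mod.active(day):
                m *= mod.multiplier
        return m

    def gain_multiplier(self, day: int) -> float:
        m = 1.0
        for mod in self.modifiers:
            if mod.metric == "gain_rate" and mod.active(day):
                m *= mod.multiplier
        return m


class SimulationConfig(BaseModel):
    """Study design plus per-group generative parameters."""

    session_days: tuple[int, ...] = DEFAULT_SESSION_DAYS
    treatment_window: tuple[int, int] = DEFAULT_TREATMENT_WINDOW
    groups: dict[str, GroupParams]
    missing_session_prob: float = Field(default=0.05, ge=0, le=1)
    reference_interval_days: float = Field(default=3.0, gt=0)
    seed: int = 0

    @field_validator("groups")
    @classmethod
    def _known_groups(cls, v: dict[str, GroupParams]) -> dict[str, GroupParams]:
        known = {group_key(a, t) for a, t in GROUPS}
        unknown = set(v) - known
        if unknown:
            raise ValueError(f"unknown group label(s) {sorted(unknown)}")
        return v

    @property
    def schedule(self) -> ImagingSchedule:
        return ImagingSchedule(self.session_days, self.treatment_window)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


def _daily_loss_prob(survival_per_interval: float, ref_days: float) -> float:
    if survival_per_interval <= 0:
        return 1.0
    return 1.0 - survival_per_interval ** (1.0 / ref_days)


def simulate_roi(
    config: SimulationConfig,
    age: str,
    treatment: str,
    roi_id: str,
    mouse_id: str,
    rng: np.random.Generator,
) -> ROITimeSeries:
    """Simulate one ROI's spine population over the imaging schedule."""
    key = group_key(age, treatment)
    if key not in config.groups:
        raise ValueError(f"no parameters configured for group {key!r}")
    params = config.groups[key]
    schedule = config.schedule
    days = schedule.session_days
    m = len(days)
    ref = config.reference_interval_days

    n_seg = int(rng.integers(params.n_segments[0], params.n_segments[1] + 1))
    seg_mean, seg_sd = params.segment_length_um
    seg_lengths = np.clip(rng.normal(seg_mean, seg_sd, n_seg), 10.0, None)
    total_len = float(seg_lengths.sum())
    segment_lengths_um = {f"seg{k}": float(v) for k, v in enumerate(seg_lengths)}

    q_day_n = _daily_loss_prob(params.survival_nascent, ref)
    q_day_p = _daily_loss_prob(params.survival_persistent, ref)

    # state arrays grow as spines form; spines present at the first session
    # are treated as established (persistent)
    n0 = int(rng.poisson(params.baseline_density * total_len))
    born = [0] * n0  # session index of first presence
    dead: list[int] = [m] * n0  # session index of first absence (m = never)
    ages = np.full(n0, params.nascent_threshold, dtype=int)
    alive = np.arange(n0)

    for j in range(m - 1):
        span = range(days[j] + 1, days[j + 1] + 1)
        surv_n, surv_p, gain_expect = 1.0, 1.0, 0.0
        for d in span:
            surv_n *= 1.0 - min(1.0, params.loss_multiplier(d, True) * q_day_n)
            surv_p *= 1.0 - min(1.0, params.loss_multiplier(d, False) * q_day_p)
            gain_expect += (
                (params.gain_rate / ref) * params.gain_multiplier(d) * total_len
            )
        p_surv = np.where(ages < params.nascent_threshold, surv_n, surv_p)
        u = rng.random(len(alive))
        died = u >= p_surv
        for idx in alive[died]:
            dead[idx] = j + 1
        alive = alive[~died]
        ages = ages[~died] + 1
        n_new = int(rng.poisson(gain_expect))
        if n_new:
            start = len(born)
            born.extend([j + 1] * n_new)
            dead.extend([m] * n_new)
            alive = np.concatenate([alive, np.arange(start, start + n_new)])
            ages = np.concatenate([ages, np.zeros(n_new, dtype=int)])

    n = len(born)
    presence = np.zeros((n, m), dtype=np.int8)
    for i in range(n):
        presence[i, born[i] : dead[i]] = 1

    # protrusion lengths: per-spine baseline with per-session jitter, kept
    # strictly above the 0.4 µm annotation rule
    base = np.clip(rng.normal(1.25, 0.30, n), 0.60, None)
    jitter = rng.normal(0.0, 0.10, (n, m))
    lengths = np.where(presence == 1, np.clip(base[:, None] + jitter, 0.45, None), np.nan)

    seg_of = rng.choice(n_seg, size=n, p=seg_lengths / total_len)
    segment_ids = [f"seg{k}" for k in seg_of]

    # session dropout: the first session is always imaged
    miss = rng.random(m) < config.missing_session_prob
    miss[0] = False
    if (~miss).sum() < 2:
        miss[1] = False
    observed_days = [d for d, gone in zip(days, miss) if not gone]
    presence[:, miss] = NOT_IMAGED
    lengths[:, miss] = np.nan

    # spines never seen at an imaged session would not exist in real
    # annotations; drop them
    seen = (presence == 1).any(axis=1)
    presence, lengths = presence[seen], lengths[seen]
    spine_ids = [f"{roi_id}_s{i:04d}" for i in range(n)]
    spine_ids = [sid for sid, k in zip(spine_ids, seen) if k]
    segment_ids = [sg for sg, k in zip(segment_ids, seen) if k]

    return ROITimeSeries(
        roi_id=roi_id,
        mouse_id=mouse_id,
        age=age,
        treatment=treatment,
        schedule=schedule,
        spine_ids=spine_ids,
        segment_ids=segment_ids,
        presence=presence,
        lengths=lengths,
        segment_lengths_um=segment_lengths_um,
        observed_days=observed_days,
    )


def _rois_per_mouse(n_rois: int, n_mice: int) -> list[int]:
    base, extra = divmod(n_rois, n_mice)
    return [base + (1 if i < extra else 0) for i in range(n_mice)]


def simulate_study(
    config: SimulationConfig, seed: int | None = None
) -> list[ROITimeSeries]:
    """Simulate a full study: every configured group at its configured size.

    All randomness flows from one seed through spawned child generators,
    so a fixed seed yields a bit-identical dataset.
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    out: list[ROITimeSeries] = []
    keys = [group_key(a, t) for a, t in GROUPS if group_key(a, t) in config.groups]
    children = root.spawn(len(keys))
    for key, child in zip(keys, children):
        age, treatment = key.split("_", 1)
        params = config.groups[key]
        per_mouse = _rois_per_mouse(params.n_rois, params.n_mice)
        roi_seeds = child.spawn(params.n_rois)
        k = 0
        for mi, n_rois in enumerate(per_mouse):
            mouse_id = f"{key}_m{mi + 1:02d}"
            for r in range(n_rois):
                roi_id = f"{mouse_id}_roi{r + 1}"
                rng = np.random.default_rng(roi_seeds[k])
                out.append(
                    simulate_roi(config, age, treatment, roi_id, mouse_id, rng)
                )
                k += 1
    return out


def write_study(
    config: SimulationConfig, out_dir: str | Path, seed: int | None = None
) -> tuple[Path, Path]:
    """Simulate a study and write ``annotations.csv`` plus a metadata
    sidecar recording the config and seed."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series = simulate_study(config, seed=seed)
    csv_path = out_dir / "annotations.csv"
    write_annotations(series, csv_path)
    meta_path = out_dir / "metadata.json"
    meta = {
        "generator": f"spinedyn {__version__}",
        "seed": config.seed if seed is None else seed,
        "config": config.model_dump(),
        "n_rois": len(series),
    }
    meta_path.write_text(json.dumps(meta, indent=2, default=list) + "\n")
    return csv_path, meta_path


# ----------------------------------------------------------------------
# scenarios

# Baseline generative parameters.  Densities and turnover magnitudes are
# literature-scale choices (cortical apical dendrites, ~0.3-0.45 spines/µm,
# a few percent turnover per 3-day interval in young adults, roughly double
# in aged animals), not values printed in any source table; gain rates are
# set to the stationary balance gain = total loss for each parameter set.
_YOUNG_BASE = dict(
    baseline_density=0.32,
    survival_persistent=0.97,
    survival_nascent=0.75,
    gain_rate=0.0156,
)
_OLD_BASE = dict(
    baseline_density=0.45,
    survival_persistent=0.95,
    survival_nascent=0.65,
    gain_rate=0.0446,
)

#: group sizes of the study design being emulated (ROIs / mice)
_GROUP_SIZES = {
    "young_vehicle": (10, 4),
    "young_THC": (12, 4),
    "old_vehicle": (17, 8),
    "old_THC": (22, 10),
}


def default_scenarios() -> SimulationConfig:
    """The four-group study design with its age and treatment effects.

    * old vs young baseline: higher density, higher gain and loss (hence
      turnover), lower stability;
    * THC in old animals: loss hazards reduced (x0.6) from day 13 through
      the end of follow-up, letting density climb above vehicle;
    * THC in young animals: a transient gain burst in the interval ending
      at day 7, followed by destabilization of nascent spines through day
      16, with no lasting density change.
    """
    groups: dict[str, GroupParams] = {}
    for key, (n_rois, n_mice) in _GROUP_SIZES.items():
        base = _YOUNG_BASE if key.startswith("young") else _OLD_BASE
        modifiers: list[TreatmentModifier] = []
        if key == "old_THC":
            modifiers = [
                TreatmentModifier(
                    metric="loss_hazard_persistent", multiplier=0.6, window=(13, 56)
                ),
                TreatmentModifier(
                    metric="loss_hazard_nascent", multiplier=0.6, window=(13, 56)
                ),
            ]
        elif key == "young_THC":
            modifiers = [
                TreatmentModifier(
                    metric="gain_rate", multiplier=2.5, window=(4, 7)
                ),
                TreatmentModifier(
                    metric="loss_hazard_nascent", multiplier=2.0, window=(7, 16)
                ),
            ]
        groups[key] = GroupParams(
            n_mice=n_mice, n_rois=n_rois, modifiers=modifiers, **base
        )
    return SimulationConfig(groups=groups)


def null_scenarios() -> SimulationConfig:
    """Four exchangeable groups: identical baseline parameters, no
    treatment modifiers, study-scale group sizes.  Used for calibration
    checks (any detected group difference is a false positive)."""
    groups = {
        key: GroupParams(n_mice=n_mice, n_rois=n_rois, **_YOUNG_BASE)
        for key, (n_rois, n_mice) in _GROUP_SIZES.items()
    }
    return SimulationConfig(groups=groups)


# ----------------------------------------------------------------------
# parameter recovery


@dataclass(frozen=True)
class LossModifierResult:
    """Estimated loss-hazard multiplier (treated / control) with a
    bootstrap percentile CI over ROIs."""

    estimate: float
    ci_low: float
    ci_high: float
    ci_level: float
    q_day_treated: float
    q_day_control: float
    n_rois_treated: int
    n_rois_control: int
    n_boot: int

    def summary(self) -> str:
        pct = int(round(self.ci_level * 100))
        return (
            f"loss-hazard multiplier = {self.estimate:.3f} "
            f"({pct}% bootstrap CI {self.ci_low:.3f}-{self.ci_high:.3f}; "
            f"daily loss prob treated {self.q_day_treated:.4f} vs "
            f"control {self.q_day_control:.4f}; "
            f"n = {self.n_rois_treated}/{self.n_rois_control} ROIs)"
        )


def _persistent_loss_counts(
    series: ROITimeSeries, window: tuple[int, int], nascent_threshold: int
) -> list[tuple[int, int, int]]:
    """Per-interval (at_risk, lost, interval_days) counts of persistent
    spines, for intervals fully inside the calendar window.

    A spine is taken as persistent at an observed session if it was already
    present at the ROI's first observed session (age unknown, assumed
    established) or first appeared >= ``nascent_threshold`` observed
    intervals earlier.
    """
    obs = series.observed_days
    cols = [series.schedule.index(d) for d in obs]
    pres = series.presence[:, cols] == 1
    if pres.shape[1] == 0:
        return []
    first_seen = np.where(pres.any(axis=1), pres.argmax(axis=1), -1)
    counts = []
    for k in range(len(obs) - 1):
        t_i, t_next = obs[k], obs[k + 1]
        if t_i < window[0] or t_next > window[1]:
            continue
        at_tis = pres[:, k]
        persistent = at_tis & (
            (first_seen == 0) | (k - first_seen >= nascent_threshold)
        )
        at_risk = int(persistent.sum())
        if at_risk == 0:
            continue
        lost = int((persistent & ~pres[:, k + 1]).sum())
        counts.append((at_risk, lost, t_next - t_i))
    return counts


def _ml_daily_loss(counts: Sequence[tuple[int, int, int]]) -> float:
    """Maximum-likelihood daily loss probability from per-interval
    (at_risk, lost, days) counts."""
    at_risk = np.array([c[0] for c in counts], dtype=float)
    lost = np.array([c[1] for c in counts], dtype=float)
    delta = np.array([c[2] for c in counts], dtype=float)
    if at_risk.sum() == 0:
        return float("nan")
    if lost.sum() == 0:
        return 0.0
    if (lost == at_risk).all():
        return 1.0

    def nll(q: float) -> float:
        s = 1.0 - q
        with np.errstate(divide="ignore"):
            ll = (at_risk - lost) * delta * np.log(s) + lost * np.log1p(
                -(s**delta)
            )
        return -float(ll.sum())

    res = optimize.minimize_scalar(
        nll, bounds=(1e-10, 1 - 1e-10), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def recover_loss_modifier(
    series: Iterable[ROITimeSeries],
    treated: tuple[str, str] = ("old", "THC"),
    control: tuple[str, str] = ("old", "vehicle"),
    window: tuple[int, int] = (13, 25),
    nascent_threshold: int = 2,
    n_boot: int = 200,
    ci_level: float = 0.90,
    seed: int = 0,
) -> LossModifierResult:
    """Estimate the persistent-spine loss-hazard multiplier of ``treated``
    relative to ``control`` inside a calendar window.

    The per-group daily loss probability of persistent spines is estimated
    by maximum likelihood from interval loss counts; the multiplier is
    their ratio.  The CI is a percentile bootstrap resampling ROIs with
    replacement within each group.
    """
    per_roi: dict[tuple[str, str], list[list[tuple[int, int, int]]]] = {
        treated: [],
        control: [],
    }
    for s in series:
        grp = (s.age, s.treatment)
        if grp in per_roi:
            counts = _persistent_loss_counts(s, window, nascent_threshold)
            if counts:
                per_roi[grp].append(counts)
    for grp, lst in per_roi.items():
        if not lst:
            raise ValueError(
                f"group {grp} has no interval inside window {window}"
            )

    def pooled_ratio(
        lists_t: list[list[tuple[int, int, int]]],
        lists_c: list[list[tuple[int, int, int]]],
    ) -> tuple[float, float, float]:
        q_t = _ml_daily_loss([c for lst in lists_t for c in lst])
        q_c = _ml_daily_loss([c for lst in lists_c for c in lst])
        ratio = q_t / q_c if q_c > 0 else float("nan")
        return ratio, q_t, q_c

    est, q_t, q_c = pooled_ratio(per_roi[treated], per_roi[control])

    rng = np.random.default_rng(seed)
    boots = []
    nt, nc = len(per_roi[treated]), len(per_roi[control])
    for _ in range(n_boot):
        bt = [per_roi[treated][i] for i in rng.integers(0, nt, nt)]
        bc = [per_roi[control][i] for i in rng.integers(0, nc, nc)]
        r, _, _ = pooled_ratio(bt, bc)
        if np.isfinite(r):
            boots.append(r)
    if boots:
        alpha = (1.0 - ci_level) / 2.0
        lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    else:  # pragma: no cover - degenerate resamples only
        lo = hi = float("nan")
    return LossModifierResult(
        estimate=est,
        ci_low=float(lo),
        ci_high=float(hi),
        ci_level=ci_level,
        q_day_treated=q_t,
        q_day_control=q_c,
        n_rois_treated=nt,
        n_rois_control=nc,
        n_boot=n_boot,
    )
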