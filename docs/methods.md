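# Methods

## Data model

The unit of observation is a spine *track*: one protrusion identified within
a region of interest (ROI) and followed across imaging sessions. Each track
carries, per scheduled session, one of three states — present, absent, or
not imaged. The distinction between "absent" and "not imaged" is structural:
an ROI skipped at a session contributes no information there, and every
downstream quantity is defined over consecutive *observed* sessions of that
ROI. Day labels are integers relative to treatment start; the default
schedule has 15 sessions (−7, −4, −1 | 4, 7, 10, 13, 16, 19, 22, 25 |
35, 42, 49, 56) and is configuration, never a hard-coded assumption.

Only protrusions strictly longer than 0.4 µm count as spines. Two filter
modes are provided because annotation practice varies: `per_session`
(default) re-evaluates the rule at every session, `per_track` applies it
once at the track's first annotation and drops the whole track on failure.
Both are idempotent; decisions are logged.

## Interval metrics

For consecutive observed sessions $(t_i, t_{i+1})$ of one ROI, spines
partition into stable, gained, and lost; the partition identities
(stable ∪ lost = present at $t_i$; stable ∪ gained = present at $t_{i+1}$)
are enforced invariants. Derived metrics:

- turnover ratio = (gained + lost) / (N(t_i) + N(t_{i+1})); undefined when
  no spine is present at either session (emitted as missing, never zero, so
  group means are not biased by empty intervals);
- lost% and stable% divide by N(t_i) and are complementary by construction;
  gained% divides by N(t_i) by default (configurable to N(t_{i+1}) — the
  convention is not universal across labs);
- transient fraction at a middle session $t_i$ of three consecutive
  observations: spines gained in the first interval and lost in the second,
  divided by N(t_i);
- spine density at an observed session: spines present / total measured
  dendrite length of the ROI (spines/µm); normalized density divides by the
  ROI's mean density over its observed baseline (pre-treatment) sessions.
  ROIs with no usable baseline are excluded with a warning.

Interval metrics are attributed to the later day of the pair; the transient
fraction is reported on the row of its first interval, i.e. at the middle
day. Group summaries weight each ROI equally (one ROI = one data point) and
report mean ± SEM.

## Spine survival

Cohorts are either all spines present at a session `d` or spines gained
between two observed sessions (absent at `d_a`, present at `d_b`), pooled
across the ROIs of a group. The event is the *first observed absence* after
entry; a spine still present at its ROI's last observed session is
right-censored there. Spines that reappear after their first absence still
count as events at that first absence (reappearances are logged); true
interval-censoring is deliberately not modeled.

The survival clock is the session index on the **scheduled** axis (1 = the
first scheduled session after entry), not calendar days and not the ROI's
own observed-session count. This choice matters: when ROIs occasionally
miss sessions, indexing each ROI's observed sessions shifts whole blocks of
that ROI's event and censoring times relative to other ROIs, which both
misaligns calendar time across ROIs and correlates observed times within an
ROI; in null simulations this inflated the log-rank false-positive rate to
≈0.07–0.08. On the scheduled axis the test is calibrated (≈0.05, see
below). Ties (many spines lost at the same session) are handled exactly by
the discrete product-limit estimator and the hypergeometric variance of the
Mantel–Cox statistic; both are implemented directly and verified against an
independent survival library to 1e-6.

Cohorts pool spines across ROIs and mice; per-mouse or per-ROI clustering is
not adjusted for, matching common practice for such survival plots. This is
a known limitation: effects concentrated in few animals will look stronger
than a cluster-aware test would report.

## Synthetic studies

The generator is a discrete-time birth–death process observed only at
scheduled sessions. Spines belong to two stability classes — *nascent*
(formed within the last `nascent_threshold` = 2 intervals) and *persistent* —
the minimal structure that reproduces both transient spines and the lower
survival of recently gained versus all spines. Survival probabilities are
specified per reference interval (3 days, the modal spacing of the default
schedule), converted to daily probabilities, and compounded across the
actual day span of each gap, so the 10-day gap after treatment behaves
consistently with the 3-day gaps. Treatment effects are multiplicative
modifiers on the daily gain rate or on a class's daily loss probability,
active inside a calendar-day window. New spines arrive as a Poisson process
proportional to the ROI's dendrite length; initial counts are Poisson at the
configured baseline density (initial spines are treated as persistent, a
mild start-up approximation). Each ROI-session is dropped (not imaged) with
probability 0.05, except the first. All randomness flows from a single seed
through spawned generators; a fixed seed gives a bit-identical dataset, and
every written dataset carries a JSON sidecar with its config and seed.

### Default scenario parameters

Group sizes mirror the emulated design exactly (old THC 22 ROIs / 10 mice,
old vehicle 17/8, young THC 12/4, young vehicle 10/4; 2–3 ROIs per mouse).
Baseline densities and turnover magnitudes are **literature-scale choices,
not published table values**: young 0.32 spines/µm with per-3-day survival
0.97 (persistent) / 0.75 (nascent), old 0.45 spines/µm with 0.95 / 0.65.
Gain rates (0.0156 and 0.0446 spines/µm per interval) are set to the
stationary balance gains = expected losses for each parameter set, giving
baseline turnover of ≈5% (young) and ≈10% (old) per 3-day interval.
Treatment effects:

- old THC: both loss hazards ×0.6 from day 13 through day 56 (effects begin
  mid-treatment and persist after it ends);
- young THC: gain rate ×2.5 during days 4–7 (a formation burst at the day-7
  interval), nascent loss hazard ×2.0 during days 7–16 (the newly formed
  spines are rapidly lost again), leaving no lasting density change.

`null_scenarios()` gives all four groups the young-vehicle parameters with
no modifiers, at study-scale group sizes, for calibration work.

### What the generator does and does not emulate

It reproduces the observables the analysis consumes: presence/absence
tracks on a realistic schedule, group sizes, age differences in density,
turnover and stability, windowed treatment effects, session dropout, and
protrusion lengths above the annotation threshold. It does **not** emulate
annotation errors (false splits/merges of tracks), spatial structure along
dendrites, correlated fates of neighboring spines, per-mouse random
effects, or sub-threshold protrusions — so passing tests demonstrate
correctness and calibration of the *analysis*, not robustness to annotation
noise or clustered biology.

## Parameter recovery

`recover_loss_modifier` estimates a treatment's persistent-spine loss-hazard
multiplier directly from annotation data: per group, the daily loss
probability of persistent spines (present at the ROI's first observed
session, or first seen ≥ 2 observed intervals earlier) is estimated by
maximum likelihood from per-interval loss counts inside a calendar window
(default days 13–25, the fully treated 3-day intervals); the estimate is
the ratio treated/control, with a percentile bootstrap over ROIs (default
200 resamples, 90% CI). In simulations with a true multiplier of 0.6 the
mean estimate over 100 studies at design scale is ≈0.60 and the nominal-90%
CI covers the truth in ≈87% of studies (slight under-coverage is expected
from percentile bootstraps over 17–22 clusters).

## Numerical conventions

- Undefined metrics (empty denominators) are NaN, never 0, and are dropped
  from group summaries.
- The log-rank statistic returns (0, p = 1) when no informative event time
  exists (e.g. self-comparison or no events), rather than 0/0.
- Output CSVs are written with fixed float formatting and deterministic row
  order; annotation CSVs use shortest-exact floats and are read back with
  round-trip float parsing, so write∘read is the identity.
- The pipeline aborts on schema violations (duplicate spine ids, presence
  at unimaged sessions, missing segment lengths), writing the violation
  report; retained sub-threshold protrusions alone do not abort because the
  filter stage handles them.

## Verification summary

The test suite checks, among others: exhaustive agreement of the fate
classification and all interval metrics with a brute-force re-derivation
over every 5-spine × 4-session presence matrix (2^20 cases, via the
column-pair/column-triple decomposition those metrics factor through);
product-limit values on hand-computed fixtures; log-rank agreement with an
independent implementation to 1e-6; a log-rank false-positive rate of
0.045–0.053 (target 0.05 ± 0.02) over 1000 exchangeable-null studies;
recovery of a known 0.6 loss-hazard multiplier to within ±0.15; one-sided
sign tests (p < 0.05 over 50 studies) for the three qualitative group
patterns of the default scenario; and byte-identical pipeline reruns. The
problem sizes used (1000 null replicates, 100 recovery studies, 50-seed
pattern batches) were chosen as the smallest giving stable Monte-Carlo
estimates of the quantities asserted.
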