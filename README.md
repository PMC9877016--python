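# spinedyn

Analysis of longitudinal dendritic-spine dynamics from chronic two-photon
imaging experiments.

In such experiments the same dendritic segments are imaged repeatedly over
weeks, every spine is annotated at every session, and annotations are
correlated across time points. The scientific questions — does a treatment
stabilize spines, does aging raise turnover, do newly formed spines persist —
all reduce to statistics of per-spine presence/absence tracks. `spinedyn`
takes those tracks as long-format CSV tables and computes the standard
quantities of the field, for example for a design with young (3-month) and
old (18-month) mice receiving a chronic low-dose THC or vehicle treatment:

- **Spine fates** between consecutive imaged sessions: *stable* (present at
  both), *gained* (present only at the later), *lost* (present only at the
  earlier); *transient* spines are gained in one interval and lost in the
  next.
- **Turnover ratio** for an interval $(t_i, t_{i+1})$:
  $\mathrm{TOR} = \dfrac{N_\mathrm{gained} + N_\mathrm{lost}}{N(t_i) + N(t_{i+1})}$.
- **Fate fractions** relative to the earlier session's spine count
  $N(t_i)$, so that lost% + stable% = 100%.
- **Spine density**: spines present divided by the total measured dendrite
  length of the region of interest (ROI), in spines/µm, optionally
  normalized to the ROI's mean density over the pre-treatment (baseline)
  sessions.
- **Spine survival**: Kaplan–Meier product-limit curves
  $S(t) = \prod_{t_j \le t} (1 - d_j / n_j)$ for cohorts of spines (all
  spines present at a session, or spines gained in a given interval), with
  right-censoring at an ROI's last imaged session, compared between groups
  by the Mantel–Cox log-rank test.

Only protrusions longer than 0.4 µm count as spines; the filter is applied
per session by default (per track optionally). Sessions an ROI was not
imaged at are first-class missing data, and "consecutive" always means
consecutive *observed* sessions for that ROI.

A discrete-time birth–death simulator (`spinedyn.simulate`) generates
complete synthetic studies — four groups (age × treatment) with configurable
gain rates, class-specific survival (recently formed *nascent* spines are
less stable than established *persistent* ones), treatment-effect windows,
and per-session dropout — so every pipeline stage is testable without any
imaging data, and known effect sizes can be recovered from the analysis
output (`recover_loss_modifier`).

## Input format

One row per spine per imaged session:

| column | meaning |
|---|---|
| `mouse_id`, `roi_id` | identifiers; an ROI is the unit of analysis |
| `group_age` | `young` or `old` |
| `group_treatment` | `vehicle` or `THC` |
| `segment_id`, `segment_length_um` | dendritic segment and its measured length |
| `spine_id` | track identity, unique within the ROI |
| `session_day` | integer day relative to treatment start (day 0) |
| `present` | 0/1 |
| `length_um` | annotated protrusion length (where measured) |

An ROI-session mentioned by no row is treated as not imaged; a spine of an
observed ROI-session with no row is absent. The default imaging schedule is
days −7, −4, −1 (baseline), 4–25 during the 28-day treatment, and 35–56
post-treatment (15 sessions), all configurable.

## Worked example

```python
import tempfile
from pathlib import Path
from spinedyn import default_scenarios, run_pipeline, RunConfig
from spinedyn.simulate import write_study

with tempfile.TemporaryDirectory() as td:
    cfg = default_scenarios()                      # four-group study design
    csv_path, meta = write_study(cfg, td, seed=1)  # synthetic annotations
    result = run_pipeline(RunConfig(input=[str(csv_path)],
                                    output_dir=str(Path(td) / "out")))
    summary = result.load("group_summary")
    print(summary[(summary.metric == "normalized_density")
                  & (summary.day == 56)].to_string(index=False))
```

prints

```
  age treatment  day             metric     mean      sem  n
  old       THC   56 normalized_density 1.284258 0.051920 21
  old   vehicle   56 normalized_density 0.879434 0.034652 16
young       THC   56 normalized_density 0.928313 0.026171 11
young   vehicle   56 normalized_density 0.899998 0.046933  9
```

i.e. four weeks after the treatment ended, spine density in treated old mice
sits ~28% above their own baseline while the other groups are at or below
theirs. The survival comparison for all spines present at day 10
(`logrank_results.csv`) shows the corresponding stabilization:

```
        cohort group_a     group_b  n_a  n_b  chi_square      p_value
present_at(10) old/THC old/vehicle 1101  793    50.91615 9.639718e-13
```

and the day-13→16 interval contrast (`interval_contrast_summary.csv`) shows
the reduced spine loss that drives it (`frac_lost` 0.059 ± 0.006 treated vs
0.094 ± 0.013 vehicle, mean ± SEM across ROIs).

The same pipeline is available from the shell:

```bash
spinedyn simulate --seed 1 --out data/
spinedyn validate data/annotations.csv
spinedyn analyze --config run.yaml
spinedyn survival data/annotations.csv --cohort gained:7:10 --cohort present:10 --out surv/
```

Outputs are tidy CSVs (`dynamics_long`, `density_long`, `group_summary`,
`survival_curves`, `logrank_results`, `interval_contrast`) plus a manifest
recording config hash, input checksums and row counts; identical inputs,
config and seed reproduce byte-identical tables.

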