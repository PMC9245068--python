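# gaitrel

Test–retest (between-day) absolute reliability of three-dimensional gait
analysis: from bilateral joint-angle and landmark time series to a full
measurement-error report, with a synthetic two-session gait-cohort generator
so every stage is testable without motion-capture data.

## The problem

Clinical gait analysis reports joint angles at specific gait events (angle at
initial contact, stance/swing extrema, range of motion) and spatiotemporal
parameters (gait speed, cadence, stride length, double-support times, ...).
Before such numbers can be used to track patients or detect pathology, one
must know the measurement error of the whole acquisition pipeline: how much
a healthy person's values fluctuate between two sessions on different days.
`gaitrel` implements the standard between-day absolute-reliability analysis
for a two-session cohort design:

- **Gait events** are detected with the coordinate-based method: initial
  contact (IC) at local maxima of the progression-aligned heel−sacrum
  anteroposterior distance, toe-off (TO) at local minima of the toe−sacrum
  distance.
- **Strides** (IC to next ipsilateral IC) are time-normalized to 101 points
  (0–100% gait cycle); each stride carries its ipsilateral TO and the
  contralateral IC/TO, which define the phase windows (stance, swing,
  first/second halves of stance, double- and single-limb support).
- **Discrete kinematic variables** — a 32-entry registry covering hip, knee
  and ankle in the sagittal, frontal and transverse planes — are reducers
  (max, min, value-at-point, range) over those windows.
- **Spatiotemporal parameters** (15 variables) come from event indices and
  heel/sacrum trajectories, including leg-length–normalized variants.
- **Reliability**: with one value per subject per session (per-stride values
  averaged within session, stride counts matched across sessions), the
  standard error of measurement is

      SEM = sqrt(MS_error)

  from the two-way subjects × sessions repeated-measures ANOVA; for two
  sessions this equals SD(d)/√2 with d the per-subject session difference,
  and both forms are computed and cross-checked on every call.
  SEM% = 100·SEM/|grand mean| is reported for spatiotemporal parameters.
  Full-curve reliability is the root-mean-square difference (RMSD) between a
  subject's two session ensemble-average curves, averaged over subjects per
  joint/plane.  An ICC(3,1)-based SEM (Weir's SD·√(1−ICC) identity) is
  available as an internal consistency oracle.

Because no raw recordings ship with the package, the `synthetic` module
generates two-session cohorts (default: 21 subjects, 7 passes per session,
60 Hz, self-selected or fastest-comfortable walking speed) with a known
additive Gaussian hierarchy of subject / session / stride effects — the
configured between-session variance is the ground-truth squared measurement
error that the pipeline must recover.

## Worked example

```python
import gaitrel as g
from gaitrel.pipeline import PipelineConfig, run_pipeline

cfg = g.SyntheticCohortConfig(n_subjects=8, passes_per_session=4,
                              strides_per_pass=4, seed=3)
report = run_pipeline(PipelineConfig(synthetic=cfg, filter_cutoff=None))
v = report.rounded().variables
cols = ["variable", "session1_mean", "session1_sd",
        "session2_mean", "session2_sd", "sem"]
print(v[v["plane"] == "sagittal"][cols].to_string(index=False))
```

prints the sagittal-plane reliability table of the simulated cohort:

```
                             variable  session1_mean  session1_sd  session2_mean  session2_sd  sem
                     hip.sagittal.RoM          47.01         4.59          46.97         4.59 2.58
          hip.sagittal.MaxFlex_Stance          26.15         3.19          26.20         2.28 1.66
           hip.sagittal.MaxFlex_Swing          28.13         3.37          28.23         2.85 1.34
           hip.sagittal.MaxExt_Stance         -18.80         3.65         -18.73         2.49 2.01
                    knee.sagittal.RoM          61.34         4.32          62.44         4.25 3.48
            knee.sagittal.MaxFlex_ST1          16.00         4.63          16.88         5.15 1.33
          knee.sagittal.MaxFlex_Swing          62.13         3.11          64.51         2.43 2.67
          knee.sagittal.MaxExt_Stance           0.82         1.85           2.13         3.67 1.83
                   ankle.sagittal.RoM          40.26         2.78          37.82         4.72 2.30
        ankle.sagittal.InitialContact          -4.81         3.93          -4.57         2.96 1.50
   ankle.sagittal.MaxDorsiflexion_ST2          13.45         3.48          11.27         5.44 1.89
ankle.sagittal.MaxPlantarflexion_STSW         -26.70         3.98         -26.47         4.82 2.30
```

Each row is one discrete variable: the two session means ± SD across
subjects (degrees) and the SEM in the same units — the expected magnitude of
between-day measurement error for that variable.  Under the default
generator settings (2° between-session angle error) the SEMs cluster around
2°, inside the conventional 2–5° acceptability band.  `report.rmsd` holds
the per-joint/plane full-curve RMSD table and `report.variables` also
carries the spatiotemporal rows with SEM%, e.g. gait speed `0.06 m/s
(4.7%)` and stance time `0.02 s (2.8%)` for this cohort.

The same pipeline runs from the command line and composes:

```bash
gaitrel simulate --seed 3 --out cohort/        # trial CSVs + ground truth
gaitrel extract  --trials cohort --out feats/  # events, strides, features
gaitrel reliability --features feats --out report/
gaitrel run --seed 3 --out report/             # all of the above in one go
```

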