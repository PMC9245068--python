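# Methods

This note documents the models, conventions and numerical choices behind
`gaitrel`, and what the synthetic cohorts do and do not emulate.

## Signals and conventions

A trial is one walkway pass: 18 joint-angle channels (left/right × hip/knee/
ankle × sagittal/frontal/transverse, degrees) and 15 landmark channels
(heel, toe, sacrum × anteroposterior/mediolateral/vertical, meters), sampled
at a fixed rate (default 60 Hz).  Flexion, dorsiflexion, adduction,
inversion/varus and internal rotation are positive; their opposites
negative.  Sample indices are 0-based; a trial of n samples spans
(n−1)/fs seconds.  The anteroposterior axis is aligned per pass: the stored
progression sign is used when present, otherwise the sign of the net sacrum
AP displacement.

## Event detection and segmentation

Initial contact is detected at local maxima of sign·(heel_AP − sacrum_AP),
toe-off at local minima of sign·(toe_AP − sacrum_AP) — the coordinate-based
variant of pelvis-referenced event detection (the velocity-based variant is
a possible extension, not implemented).  Peak finding uses strict discrete
local extrema (plateaus count once, at their first index) followed by
refractory suppression: candidates closer than 0.4 × the median
inter-candidate interval are suppressed keeping the larger magnitude, ties
breaking toward the earlier index.  These semantics are deliberately simple
enough to check against an exhaustive oracle.  At most one toe-off is kept
per inter-IC interval (largest magnitude), which enforces IC/TO alternation
by construction.

A 4th-order zero-lag Butterworth low-pass (default cutoff 6 Hz, standard for
gait landmarks at these rates) can be applied to all channels before
detection and extraction; it is configurable and off for synthetic
noise-free data, which needs none.

Strides are windows between consecutive ipsilateral ICs, inclusive of both
bounding samples.  A stride must contain its ipsilateral TO and (when the
contralateral side is supplied) one contralateral TO and IC in the order
IC < cTO < cIC < TO < next IC; windows failing this are dropped with a
logged reason.  Automated quality checks replace manual stride review:
strides whose duration deviates more than 40% from the trial median, or
whose stance fraction falls outside (0.4, 0.8), are dropped and logged.
Time normalization linearly resamples each stride onto 101 points (1% phase
steps), preserving endpoints exactly.

## Discrete variables

Each registry entry is a reducer over a phase window: stance [0, TO), swing
[TO, 1], stance halves split at midstance = TO/2, double-support windows
from the contralateral events (DLS1 + SLS + DLS2 partitions stance exactly),
midswing = (TO+1)/2.  Window endpoints are included when reducing;
value-at-point reads the sample nearest the named phase (the grid is 1%
steps, so no second interpolation); range is max − min over the full cycle.
Extension/abduction/eversion/external-rotation/plantarflexion extrema are
signed minima — no absolute values anywhere.  Two definitions were genuinely
open and were fixed as follows:

- the stance-to-swing plantarflexion window is [midstance, TO + 0.2·swing],
  since the plantarflexion trough sits at or just after toe-off;
- the ankle frontal-plane "MaxExt_Swing" entry has no standard textual
  definition; it is implemented as the signed minimum over swing
  (eversion-direction extremum) and flagged ambiguous in the registry rather
  than silently renamed.

## Spatiotemporal parameters

Temporal parameters come from event sample indices; swing time and
single-limb-support time are the closing differences (stride − stance and
stance − DLS1 − DLS2), so the partition identities hold exactly, bit for
bit, on every stride.  Stride length is the heel AP displacement between
bounding ICs; step length/width compare ipsilateral and contralateral heel
positions at the ipsilateral IC; step time runs from contralateral IC to
ipsilateral IC.  Gait speed is measured from sacrum AP displacement over the
stride rather than as stride length / stride time, so speed and length are
independent measurements and their ratio is a diagnostic.  Cadence is
120 / stride time (steps per minute under step symmetry, consistent with
single-leg analysis).  Leg-length variants divide by leg length and are
reported as dimensionless multiples of it (the `_ll` speed is 1/s), even
where conventional tables print them with the raw units.  Gait speed is
computed per stride and averaged within session; whether a pass-level
average would be preferable is unknowable from the design and the
difference is far below the between-session error.

## Reliability statistics

The unit of analysis is one value per subject per session.  Per-stride
values are first truncated to the earliest min(n₁, n₂) valid strides per
subject (deterministic, seed-free) and then averaged within session.
SEM = √MS_error from the two-way subjects × sessions ANOVA with one
observation per cell; for two sessions this equals SD(d)/√2 and both forms
are asserted equal on every call (the grand mean is computed as the mean of
column means so the residual — and hence the SEM — is exactly zero for
identical sessions, not merely zero to rounding).  SEM% divides by the
absolute grand mean of the two session means and is undefined (NaN, with a
warning) when that mean is zero.  The ICC cross-check computes ICC(3,1) and
SD_pooled·√(1−ICC) with the pooled variance taken as
(SS_subjects + SS_error)/(k(n−1)) — the decomposition under which the
identity with √MS_error is algebraic, which the tests verify to 1e−6.
Report output rounds SEM to two decimals and SEM% to one; all internal
computation keeps full precision.  Angle errors at or below 5° are labelled
acceptable, following the conventional 2–5° band for gait kinematics.

Full-curve reliability: per subject, the within-session ensemble average
(pointwise mean across matched strides) is formed for each joint/plane; the
RMSD between the two session curves is averaged over subjects.  Note that
between-session RMSD differences two independent session error curves, so
under a shared error source of SD σ its scale is √2·σ while the discrete
SEM recovers σ; the pipeline test asserts exactly this √2 relationship.

## The synthetic cohort generator

The generator emulates the structure of a two-session overground study:
n subjects (default 21) × 2 sessions × several passes (default 7, within
the reported six-to-eight range) of a few strides each (default 4 — within-
pass stride counts are not reported for such protocols; this is an explicit
guess), at 60 Hz, for a self-selected or fastest-comfortable speed task,
with leg length 0.84 m.  Default spatiotemporal means follow the reported
healthy-adult magnitudes per task (e.g. self-selected gait speed 1.35 m/s,
stride length 1.43 m, stance 0.74 s, double supports 0.18 s, step width
0.19 m).  Stride time is derived as stride length / gait speed; printed
cohort tables are not exactly self-consistent at that precision, so the
generator's implied stride time (1.06 s) and cadence (~113 steps/min) differ
slightly from the corresponding printed values — a property of the
configured means, kept deliberately.

Every variable follows an additive Gaussian hierarchy: population mean +
subject effect + session effect + stride effect, with variances configured
per variable.  Both sessions draw independent session effects, so
√var_between_session is the ground-truth SEM the pipeline must recover (a
one-sided "session 2 = session 1 + error" scheme would make √MS_error
converge to σ/√2 instead).  Spatiotemporal draws are rejection-sampled to
plausibility (positive times, stride time 0.3–3 s, stance fraction
0.45–0.78, each double support under 40% of stance) with at most 100
retries before a loud failure — no silent clipping at the stride level.
Default variance components: subject-level SDs follow healthy between-
subject spreads (angles 3°, speed 0.25 m/s, ...), session-level SDs sit at
reported between-day error magnitudes (angles 2°, speed 0.06 m/s, ...), and
stride-level SDs reflect steady-state within-pass variability (angles 0.5°,
times ~10–15 ms).

Angle curves are truncated Fourier templates (4 harmonics per joint/plane)
fit once to keypoint sketches of normal adult gait so ranges of motion and
extremum locations match reported magnitudes.  Angle errors at each
hierarchy level are low-order harmonic random curves
(c₀ + 1st + 2nd harmonic, variance weights 0.5/0.3/0.2) whose pointwise SD
is exactly the configured σ at every phase — so the injected σ is the
ground-truth error of every discrete variable, including ranges of motion,
which a pure curve offset would leave error-free.  Generated curves are
time-warped so the template's nominal stance fraction (0.65) maps onto each
session's actual stance fraction, keeping curve features locked to the gait
events as they are physiologically; without this, extrema drift relative to
the moving phase windows and spurious session variance appears at steep
window boundaries.

Landmark trajectories are built so the coordinate-based detector has
well-defined extrema exactly at ground truth: the analysis (dominant) side
carries the reference event clock (ICs at cumulative stride times, TOs at
IC + stance); the contralateral side is derived from the double-support
draws and absorbs residual timing asymmetry, which the dominant-side
analysis never measures.  Heel/toe AP positions are a monotone sacrum
progression (piecewise-constant per-stride speed, integrated exactly so the
displacement per stride equals the drawn stride length) plus a cosine
oscillation peaking at that side's ICs (heel) and troughing at TOs (toe),
amplitude stride length/4.  Lead-in and lead-out margins (0.1 and 0.25
stride periods) are chosen so no spurious extremum can enter the signal
ends under the rejection bounds.  Passes alternate walking direction.
Vertical channels are schematic (smooth swing bumps) and are not used by
the pipeline.

All randomness flows from one seed through named subject/session/pass
streams (`numpy` `SeedSequence` spawn keys), so identical config + seed is
bit-identical and adding subjects does not perturb existing ones.

What the generator does **not** emulate: pose-estimation noise structure of
video-based capture, soft-tissue artifact, turns and acceleration at
walkway ends (strides are steady-state), left/right template asymmetry, and
non-Gaussian or heteroscedastic error.  Passing tests therefore demonstrate
that the pipeline's estimators are correct and unbiased under the stated
hierarchy at realistic magnitudes — not that any particular capture system
achieves these errors on real data.

## Problem sizes

The default test and acceptance runs use cohorts of 2–21 subjects, 2–7
passes per session and 3–4 strides per pass (up to ~350 trials of ~350
samples), 200 Monte-Carlo cohorts for estimator recovery, and 500 random
curves for oracle equivalence — sizes at which every Monte-Carlo tolerance
in the suite is a ≥3-standard-error bound.

## Known limitations

- The C3D reader requires the optional `ezc3d` dependency and maps marker
  labels only; joint angles must be supplied separately.
- Event detection assumes steady-state level walking with a monotone
  progression per pass; treadmill and turning gait are out of scope.
- SEM% is reported for spatiotemporal parameters only (angle means cross
  zero, where a percentage is meaningless).
- Minimal detectable change, Bland–Altman limits and curve-level statistical
  parametric mapping are natural extensions, deliberately not included.
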