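# Methods

## The measurement model

`movemetrics` quantifies arm/hand motor performance from a forearm armband
recording eight surface-EMG channels at 200 Hz and a six-axis inertial unit
(three-axis accelerometer, three-axis gyroscope) at 50 Hz. Subjects perform
six protocol movements with each hand: hand rotation with the elbow extended
(RH-EE) or flexed (RH-EF), object grasp-pick-place with an easy (GPP-EL) or
heavy (GPP-HL) load, and the proximal (TT-P) and distal (TT-D) tapping tasks.

Each trial is reduced to seven window-level *basic measurements*:

* EMG, on the filtered signal `x(t)` of the channel of interest, per window
  of `W` samples: mean absolute value `MAV = (1/W) Σ|x(t)|`, variance
  `VAR = (1/W) Σ x(t)²` (defined as the mean square — no mean subtraction),
  waveform change `WC = Σ |x(t+1) − x(t)|`.
* ACC and GYRO, on the time-derivative `ẋ(t)` of the axis of interest:
  simple square integral `SSI = Σ ẋ(t)²` and range
  `RAN = max ẋ − min ẋ`.

A *movement performance indicator* (MPI) is one basic measurement aggregated
(arithmetic mean by default; median and sum are selectable) over the sliding
windows of one (movement, hand) trial. With 7 measurements × 6 movements ×
2 hands this yields exactly 84 MPIs per subject.

## Preprocessing

Signals are low-pass filtered with a zero-phase (forward–backward)
Butterworth filter: order 4 / 20 Hz cutoff for EMG, order 3 / 5 Hz for ACC
and GYRO. Zero-phase application was chosen because the analysis is offline
and group delay would misalign the EMG and IMU window grids; the effective
attenuation order doubles relative to a single pass.

Quiet lead-in and lead-out are trimmed by an energy threshold: window
energies `E_w = Σ x²` are computed in consecutive non-overlapping 250 ms
windows on the channel-summed squared signal, and the retained span runs
from the first to the last window with `E_w ≥ 0.4 · max_w E_w`. Indices are
0-based and half-open. EMG and IMU streams are segmented independently
(their clocks differ); within the IMU stream, accelerometer and gyroscope
rows are RMS-normalized before the joint energy computation so that neither
unit system dominates. The 250 ms energy window is short relative to the
shortest repetition and makes the boundary resolution ± one window.

A consequence worth knowing: when an amplitude decrement is strong, the
threshold trims the decayed tail of the trial (every window below ~0.63 of
the peak amplitude), capping the *observable* within-trial decline at about
37 % regardless of the true per-repetition decrement. Trend-detection power
is therefore not monotone in the decrement beyond roughly 5 %/repetition —
stronger decay shortens the retained series faster than it steepens it.

## Windowing

Window lengths are 200 ms for EMG and 800 ms for ACC/GYRO, with a 25 %
overlap (50 ms and 200 ms respectively). In samples both become windows of
40 with step 30, since the printed millisecond values are exact multiples of
both sampling intervals (ms → samples by `round`). A window count of
`floor((T − W)/step) + 1` full windows is used; a trailing remainder shorter
than one step is discarded. The IMU derivative is computed once on the
segmented, filtered axis signal and then windowed (window boundaries lose no
interior samples; the derivative series is one sample shorter). It is scaled
to physical units/second, making SSI and RAN sample-rate invariant up to
discretization.

## Channel and axis of interest

EMG measurements use channel 2 for right-hand movements and channel 6 for
left-hand movements — the electrodes over the external forearm muscles,
which show the largest patient–control mean differences. This convention is
fixed by default (it was established by a one-time all-channel analysis,
reproducible via `mpi.emg_channel_group_differences`). ACC/GYRO measurements
use a per-movement axis of interest, either the documented fixed map
(default) or data-driven selection: the axis maximizing the absolute
patient–control group-mean difference of the trial-aggregated measurement,
with a two-sided rank-sum check reported alongside and ties broken to the
lowest axis index. When using data-driven selection in a reusable pipeline,
select on a dedicated reference cohort and freeze the map before any
cross-validated classification, otherwise held-out labels leak into feature
construction.

## Reliability

Split-half reliability is estimated within-trial: the window series is split
into odd- and even-indexed windows, each half is aggregated like a normal
MPI, and the half-scores are correlated across subjects with ICC(2,1) — the
two-way random-effects, absolute-agreement, single-measure intraclass
correlation computed from the ANOVA mean squares. The odd/even interleave is
deliberately robust to slow temporal trends (the bradykinesia sequence
effect would confound a first-half/second-half split). No Spearman–Brown
correction is applied; the reported quantity is the ICC of the half-scores.
ICC is undefined (flagged NaN) when the between-subject variance vanishes;
at least 5 subjects are required.

## Group statistics and laterality

MPI distributions fail Lilliefors-type normality checks at realistic cohort
sizes, so comparisons are nonparametric: the two-sided Wilcoxon rank-sum
test (exact enumeration when the smaller sample has ≤ 10 tie-free
observations, tie-corrected normal approximation otherwise) and Spearman's
ρ (exact permutation p for tie-free n ≤ 9, t-approximation otherwise).

The laterality analysis flags MPIs that separate the affected from the
unaffected hand in patients while staying symmetric in controls. Patients'
hands are oriented affected/unaffected before pooling left- and
right-affected subgroups (a per-subgroup mode exists). Two design choices
depart from a literal unpaired reading of the protocol and are deliberate:

1. **The default hand comparison is the paired Wilcoxon signed-rank test.**
   Hands are paired within subject; between-subject amplitude spread is
   common to both hands and the paired test removes it. With an unpaired
   rank-sum test at per-stage group sizes of 5–15, the between-subject
   spread swamps a 15 % stage-1 asymmetry and the analysis has essentially
   no power. The unpaired variant remains available (`test="unpaired"`).
   Note the paired test needs ≥ 6 pairs for p < 0.05 to be attainable.
2. **The stage-trend condition uses the within-subject unaffected/affected
   ratio**, not the absolute left-right difference. Under a joint amplitude
   decline and asymmetry growth, the absolute difference of a degree-2
   measurement (VAR, SSI scale quadratically with amplitude) is provably
   non-monotone across stages, so an absolute-difference criterion would
   reject exactly the planted pattern it is meant to find. The ratio
   isolates asymmetry from the overall decline; absolute differences are
   still reported in the evidence.

The stage-wise predicate is true iff every stage group shows a significant
affected < unaffected difference, stage means of the subject-level MPI
strictly decrease from stage 1 to 3, and stage means of the
unaffected/affected ratio strictly increase. P-values across the 84 MPIs are
reported raw, with an optional Benjamini–Hochberg flag.

Clinical-scale screens follow fixed threshold pairs: an MPI correlates with
the tapping counts if ρ ≥ 0.5 with p < 0.05 (positive: better performance,
more taps) and with UPDRS-III scores if ρ ≤ −0.5 with p < 0.05 (negative:
higher score, worse impairment).

## Feature selection and classification

The LDA informativeness index ranks standardized features by the absolute
discriminant-weight mass of a shrinkage-regularized (Ledoit–Wolf) linear
discriminant; the cumulative normalized index gives the smallest top-k set
retaining a requested fraction of discriminative weight. This index is this
package's reconstruction — the ranking is defined here as absolute
standardized discriminant-weight mass, since only the concept, not the
formula, is standard. The LASSO screen fits L1-penalized logistic
regressions over λ ∈ [0.01, 0.5] (per-sample penalty; scikit-learn
`C = 1/(λ·n)`) and reports the nonzero-coefficient set per λ.

Classification covers the diagnosis task (patients vs controls) and three
one-vs-all staging tasks (controls excluded), with six classifiers:
logistic regression, decision tree, RBF-kernel SVM, k-nearest neighbours
(k = 10), Gaussian naive Bayes, and a multilayer perceptron with two hidden
layers of four nodes. Hyperparameters not fixed by the protocol are pinned
for reproducibility (logistic C = 1, tree min-leaf 2, SVM C = 1 with scaled
γ, MLP ReLU / max 2000 iterations / fixed seed) and recorded in result
metadata. Evaluation is stratified 10-fold cross-validation scored by ROC
AUC (mean and SD over folds); stratification is necessary because stage
groups are small. When the LDA screen is combined with classification it is
refitted inside each training fold. A task whose smallest class has fewer
members than folds raises a clean error rather than silently reducing folds.

## Bradykinesia

Slowness is the energy-segmented active duration of a trial. The gyroscope
stream is the default duration sensor: angular velocity tracks the movement
itself, while EMG burst energy fluctuates with the stochastic
muscle-activity carrier and yields noisier endpoints.

The sequence effect — progressive per-repetition amplitude decline — is
operationalized as the ordinary-least-squares slope of the window series
against window index divided by the series mean (a dimensionless fractional
change per window, invariant to signal rescaling), with the two-sided t-test
of the slope as the trend test; a Mann–Kendall option is provided. A
negative slope with p < 0.05 is reported as a detected sequence effect. The
analysis defaults to the tapping trials (30 s of data) and reports both the
`emg-mav` and `gyro-ssi` series. The `gyro-ssi` series is the best-behaved
trend carrier: it integrates the squared derivative over 800 ms windows, so
its noise is small and the OLS t-test is well calibrated (false-positive
rate ≈ 2–3 % at the 5 % level in null simulations). The raw-EMG `mav`
series carries narrowband carrier noise and 25 %-overlap window
autocorrelation that make the same test anti-conservative at the margin
(null rate up to ~10 %); an autocorrelation-corrected variant was evaluated
and rejected because it restores the null at a large sensitivity cost.

## The synthetic cohort generator

No recordings are distributed with the protocol, so the generator emulates
the cohort structure (16 controls; 17 patients across Hoehn–Yahr stages
1–3 with an affected side, by default 6/6/5) and the planted effects the
analyses assume. Per (subject, hand) severity resolves to:

| parameter | default | meaning |
|---|---|---|
| `amplitude_ratio` | 0.7 / 0.55 / 0.4 | patient/control burst amplitude per stage |
| `slowness_factor` | 1.2 / 1.4 / 1.7 | repetition-period multiplier per stage |
| `decrement_per_rep` | 0.05 | burst k scaled by (1−d)^k in patients |
| `asymmetry_factor` | 0.85 / 0.7 / 0.55 | affected/unaffected amplitude ratio per stage |
| `rep_consistency` | 0.05 | CV of per-repetition amplitudes (drives split-half ICC) |
| `subject_sd` | 0.2 | log-scale SD of the per-subject amplitude factor |
| `period_jitter` | 0.05 | log-scale SD of the per-subject period factor |
| `noise_sd` | 0.02 | additive sensor noise, fraction of base amplitude |

EMG trials are per-channel gain × burst envelope × unit-RMS Gaussian noise
band-limited to 5–95 Hz, plus white sensor noise. Channel gains peak on
channel 2 (right hand) / channel 6 (left hand). The envelope is one
raised-cosine-tapered (Tukey, taper 0.4) pulse per repetition with ≥ 1 s of
quiet padding at both ends; tapping movements add a tonic floor of 0.6
(muscles do not fully relax during ~1 Hz alternation, and through a 20 Hz
low-pass the resulting MAV series is smooth, as it is in practice). IMU
trials are a movement-frequency sinusoid plus its first harmonic on a fixed
movement-specific dominant axis (documented map; e.g. RH-EE → ACC y,
GYRO x), 20 % quadrature leakage onto the other axes, the same envelope, and
sensor noise. Protocol timing: hand rotations run 10 s, grasp-pick-place is
repeated exactly 5 times at a 1 s base period (slowness stretches the trial),
tapping alternates for 30 s at base periods of 1.2 s (TT-P) and 1.0 s (TT-D)
— deliberate, elderly-paced values which also keep the planted decrement
observable within the energy-segmented span. Clinical scores are monotone
functions of severity with noise (`updrs3_total ≈ 8 + 11·stage + N(0,3)`,
tap counts ≈ base rate × 30 s × amplitude ratio × subject factor); they are
calibrated for ordering only, not clinical realism.

Determinism: the seed fixes the cohort bit-for-bit via per-subject spawned
generators; the label structure (IDs, groups, stages, affected sides — a
deterministic right, right, left cycle giving the ~2:1 clinical ratio) is
computed without randomness and is identical across seeds.

What the generator does **not** model — and what passing tests therefore do
not show about real data: motor-unit physiology, tremor, movement artifacts,
electrode lift-off, nonstationary noise, inter-session electrode placement
variability, or correlations between movements beyond the shared subject
factor. Detection rates and AUCs on this cohort characterize the pipeline's
ability to recover effects of the planted form and size, not clinical
performance.

## Numerical and degenerate-input conventions

* ms → samples conversion by `round()`; sample indexing 0-based, half-open.
* All-zero signals raise a segmentation error; trials shorter than one
  window are rejected at construction, not repaired (no imputation).
* Axis-selection ties break deterministically to the lowest axis index and
  are flagged.
* A window series with fewer than 2 windows cannot be split-half scored; a
  series with fewer than 5 windows has no trend test; a zero-mean series has
  an undefined normalized slope (flagged NaN).
* Raw signed EMG samples in arbitrary device units are assumed; no
  rectification or millivolt calibration is attempted.

## Problem sizes used in the checks

The built-in verification suites run at desk scale, chosen to keep the
planted-effect simulations well-powered: reliability on 30 subjects;
diagnosis classification on 20 + 20; laterality predicate rates over 100
seeded replicates at 15 subjects per compared group; sequence-effect rates
over 100 replicates of single tapping trials; axis-recovery over 100
replicates at 15 + 15. The acceptance script reports the minimum split-half
ICC across all 84 MPIs on the 30-subject cohort.

## Known limitations

* The laterality predicates assume a consistent affected-side orientation;
  cohorts in which stage groups differ systematically in affected side are
  pooled after orientation, which discards any side-specific biology.
* The energy threshold's truncation of strongly decaying trials (above)
  biases tapping MPIs of severe patients toward their early, stronger
  repetitions.
* Frequency-domain features, tremor metrics, OFF-state analysis and
  balance/stability are out of scope.
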