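# Methods

This note documents the models and numerical procedures behind `swayrqa`:
what the synthetic-trial generator assumes, how each analysis stage is
defined, which defaults were chosen where the design was genuinely open, and
what the package's tests do and do not establish about real data.

## The task and the protocol

A participant stands on a platform translating sinusoidally in the
medio-lateral (ML) direction with 20 cm peak-to-peak amplitude (half-amplitude
10 cm; the convention is configurable since amplitude reporting in platform
paradigms is ambiguous).  A trial is a frequency staircase: 15 s quiet
standing, six full cycles at each of 0.2, 0.4, 0.6, 0.8, 1.0, 1.2 Hz
ascending, then 1.0 → 0.2 Hz descending (the top step is not repeated), then
15 s quiet standing.  At 100 Hz sampling this is exactly 172 s and 17 200
samples; the 11 moving epochs are the analysis conditions.  Epoch boundaries
are cut from the protocol clock — platform and kinematics are assumed
trigger-synchronized — with half-open 0-based sample ranges that tile the
trial without gaps.

## Synthetic-trial generator

No public motion-capture data accompanies the paradigm, so the generator is
a first-class, tested component that emulates the statistical structure the
analysis is designed to detect.

**Platform.**  A piecewise sinusoid whose phase accumulates continuously
across frequency steps (a real motor does not reset phase); identically zero
during quiet epochs.

**CoM, tracking regime.**  While coupled, the CoM is a lagged, low-passed,
saturating copy of the drive:

    com_track(t) = A_c · tanh( g(f) · platform(t − lag_per_hz·f) / A_c )

* `comfortable_amplitude` A_c = 6 cm: the excursion a standing person will
  ride the platform over; beyond it the response saturates (the platform
  half-amplitude is 10 cm, so saturation is engaged at every moving epoch).
* `gain_rolloff_hz` = 0.8 Hz: first-order magnitude roll-off
  g(f) = 1/√(1+(f/0.8)²).  The standing body is mechanically low-pass; it
  follows a 0.2 Hz drive almost fully but responds at reduced gain at 1 Hz.
* `lag_per_hz` = 0.1 s/Hz: postural tracking lags grow with drive frequency.

**CoM, intermittent decoupling.**  A two-state Markov chain switches between
tracking and quasi-static holds.  The per-sample decoupling hazard is

    p_dec(f) = p_decouple · max(0, f − decouple_onset_hz),

zero below the onset (default 0.5 Hz, inside the 0.4–0.6 Hz band where ML
CoM–platform coordination is known to change phase mode) and growing
linearly with frequency above it (default slope 0.05 per sample per Hz).
Recoupling has constant probability `p_recouple` = 0.002 per sample, so
trapped states last seconds (mean 5 s) — long relative to the 1.25 s span of
an embedded state vector, which is what makes them visible as laminar
structure.  At 1.0 Hz the stationary hold fraction is ≈ 93%: above the
transition band the person predominantly lets the platform slide underneath
and re-entrains only episodically, which is the intermittent-coupling
behaviour the analysis targets.

**CoM, intrinsic sway.**  A held CoM does not freeze; it wanders with the
low-frequency sway of quiet stance.  During holds the CoM follows
`held + sway(t) − sway(t₀)`: a Gaussian process low-passed at
`sway_cutoff` = 0.5 Hz and scaled to `sway_sd` = 0.8 cm, entered
continuously at the moment of decoupling.  Sway is attached to the decoupled
state only; during active tracking the platform-locked response dominates
the ML trajectory.  This matters doubly for the cross-recurrence geometry:
a strictly frozen state would generate no cross-recurrences at moderate
radius (the embedded platform loop never approaches constant-coordinate
states once the delay spans an appreciable phase angle), whereas a slowly
wandering state produces the long vertical lines that characterize laminar
episodes once the fixed-rate calibration pushes the radius up.

**Measurement noise.**  White Gaussian noise (`noise_sd` = 0.3 cm) low-passed
at 4 Hz, matching the analysis filter band.

**Randomness.**  All streams (regime chain, sway, noise, segment
perturbations) derive from one integer seed through numpy `SeedSequence`
spawn keys, so every trial and stream is independently reproducible; the
pipeline derives per-(subject, trial) seeds the same way.

**Segment decomposition.**  For round-trip testing of the whole-body CoM
computation, a trial CoM can be split into 13 segment trajectories
(Dempster mass fractions: head-and-trunk 0.578 plus paired limb segments)
whose perturbations are projected to have exactly zero mass-weighted sum.

## Preprocessing

Signals are filtered with a second-order Butterworth low-pass at 4 Hz,
applied forward and backward (`scipy.signal.filtfilt`).  Zero-phase
filtering is a deliberate choice: phase distortion would corrupt the
CoM–platform phase relation that the recurrence analysis quantifies.  The
cost is a squared magnitude response, |H(f)|², which the tests verify against
the closed form.  No transient is trimmed inside epochs by default (a `trim`
option exists).

## Embedding parameters

* **Delay (AMI).**  Mutual information between the series and its lagged
  copy from an equal-width 2-D histogram with ⌈√(N/5)⌉ bins per axis.  The
  histogram is averaged over a 4×4 set of phase-shifted bin grids: plain
  binning resonates with strongly periodic signals (which visit only a
  finite set of values) and produces ripple that traps a naive
  first-local-minimum rule.  The delay is the first local minimum of the
  lightly smoothed curve; when that minimum lies in a flat valley (within
  1.5% of the valley floor, relative to the lag-0 drop) the centre of the
  valley is reported, which pins the quarter-period delay of periodic
  signals.  A curve with no local minimum falls back to the global argmin
  with a warning; a constant signal raises a distinct zero-information
  error.
* **Dimension (FNN).**  Abarbanel's false-nearest-neighbour criteria with
  the conventional thresholds (distance-growth ratio 15, absolute-size
  criterion 2× the signal SD, 1% acceptance).  A numeric floor (10⁻⁸ of the
  signal SD) on the ratio criterion prevents exact periodic twins — pairs at
  float-rounding distance — from being miscounted as false.  Noise-like
  signals never fall below the acceptance threshold and are reported with a
  warning rather than a spurious dimension.
* **Pooling.**  Analyses use one (m, τ) per study.  After discarding
  1.5×IQR outliers, m pools by maximum (an embedding sufficient for every
  series) and τ by rounded median (mean available).  The analysis defaults
  m = 6, τ = 25 samples are used throughout unless estimation is requested.

## Cross-recurrence quantification

* **Matrix.**  R_ij = 1 iff ‖a_i − b_j‖₂ ≤ ε, inclusive threshold (which
  makes the sorted-distance oracle exact).  Rows index the CoM trajectory,
  columns the platform.
* **Normalization.**  Both epoch series are z-scored before embedding;
  cross-recurrence between signals of different amplitude is
  radius-meaningless otherwise.  The reported radius is therefore in
  z-units.
* **Radius calibration.**  RR(ε) is non-decreasing (set inclusion), so the
  target rate 2.5% is bracketed by geometric expansion from ε₀ = 0.01 and
  then bisected until |RR − 0.025| ≤ 0.001 or the bracket is below 10⁻⁹.
  An unreachable target (too few distinct distances) returns the nearest
  achievable rate flagged as non-converged.
* **Lines.**  Maximal 1-runs along diagonals (parallel evolution) and along
  columns (CoM holding near one platform state).  Minimum counted length 2
  in both directions; border runs count at observed length.  The
  conservation identity Σ l·H(l) = Σ R_ij (all l ≥ 1, both directions) is
  used to validate histogram/matrix consistency at computation time.
* **Measures.**  DET and LAM as line-point fractions; mean line lengths and
  Shannon entropies over the l ≥ min_len distributions.  Entropies are in
  nats by default (the defining formula uses ln); a bits flag is provided.
  Degenerate cases use fixed sentinels: with recurrent points but no
  qualifying lines DET/LAM = 0, and empty line distributions report mean
  line 0 and entropy 0.
* **Epoch driver.**  `crqa_epoch` (and the `CrossRecurrence` model class it
  wraps) runs normalize → embed → calibrate → measure per epoch; epochs too
  short to embed raise a typed error that the pipeline logs and skips.

## Statistics

Epoch measures are averaged per subject × condition (the staircase's 11
moving conditions, ascending and descending limbs kept separate) into
complete tables; missing cells are an error naming the offending cell.  The
frequency effect is tested with a classical one-way repeated-measures ANOVA
(statsmodels `AnovaRM`), df = (k−1, (k−1)(n−1)); for 11 participants and 11
conditions that is (10, 100).  Sphericity corrections are off by default to
match the uncorrected reporting convention; a Greenhouse–Geisser option
computes ε from the condition covariance matrix and adjusts the p value
only.  Tables with zero error variance short-circuit to F = ∞ with a
degeneracy flag.  Post-hoc pairwise procedures are out of scope.

## What the synthetic tests do and do not show

The generator reproduces the directional findings the analysis is built to
detect, and the test suite asserts them on ten seeded default trials: mean
vertical line increases and both line entropies decrease from the 0.2 Hz to
the 1.0 Hz condition, DET at 1.2 Hz sits below DET at 0.2 Hz, the calibrated
radius grows with frequency, and DET/LAM stay near 100% everywhere.
Condition-level comparisons average a frequency's ascending and descending
epochs within a trial, mirroring how per-frequency conditions are read out
of the staircase.

The generator is a phenomenological surrogate, not a biomechanical model.
It has no inverted-pendulum dynamics, no anterior-posterior coupling, no
marker-level kinematics, no inter-subject anthropometric variation, and its
regime switching is memoryless.  Passing trend tests therefore show that the
pipeline detects the intended dynamical signatures when they are present at
realistic amplitudes and time scales — not that real postural data contains
them.  Absolute measure values (e.g. mean line lengths) depend on epoch
length and on generator amplitudes and should not be compared against
human-subject numbers.

## Problem sizes and runtime

Default analyses embed up to 2875 points per epoch (0.2 Hz, 3000 samples),
for which the full distance matrix (≈ 8×10⁶ entries) is computed once per
epoch and reused across the calibration bisection.  A full 11-epoch trial
analyzes in well under a second on one core; the ten-trial trend suite runs
in seconds.  The pipeline's simulated studies default to small subject/trial
counts; an 11-subject × 12-trial study at full scale runs in minutes.

## Known limitations

* The AMI valley of noiseless periodic signals is intrinsically flat at the
  histogram's resolution; the reported τ is the valley centre, with ±2–3
  samples of estimator ambiguity.
* Radius calibration reports the rate actually achieved; with very short
  epochs (the 1.2 Hz epoch has 250 embedded points) the discrete distance
  spectrum can make the ±0.1 percentage-point band the binding constraint.
* The repeated-measures ANOVA assumes complete tables; unbalanced designs
  are rejected rather than imputed.
* Whether the historical analyses z-scored the series or used another
  normalization is not documented; the package's radii are defined on
  z-scored data and are not directly comparable to radii on raw centimetre
  data.
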