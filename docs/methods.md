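# Methods

## The classification problem

Radial pulse diagnosis distinguishes pulse *types* — morphological
categories of the arterial pressure waveform at the wrist.  This package
classifies seven: four single types (slippery, flat, thready, stringy) and
three compounds (thready-slippery, thready-stringy, stringy-slippery).
Compound types blend the morphology of their constituents, which is what
makes the task hard: a thready-stringy pulse shares the wide main wave of
the stringy pulse and the low amplitude of the thready pulse, and most
misclassifications fall between a compound and one of its constituents.

Inputs are single-channel pressure recordings sampled at 720 Hz (about
60 s per acquisition in the reference protocol).  The classifier operates
on one representative cycle per recording.

## Synthetic waveform model

No public dataset of labelled seven-type pulse recordings exists, so the
package generates its own.  Each cycle is a sum of three positive
unimodal component waves on a zero baseline, the standard arterial pulse
decomposition:

* **main (percussion) wave** — an asymmetric Gaussian (separate rising and
  falling standard deviations), peak = fiducial B.  The fast rise and slow
  fall reproduce the systolic upstroke.
* **tidal (pre-dicrotic) wave** — a symmetric Gaussian on the falling
  limb (fiducials C/D).
* **dicrotic wave** — a late symmetric Gaussian separated from the tidal
  wave by the dicrotic notch (fiducials E/F).

Centres and widths are fractions of the cycle, so morphology is
period-invariant; amplitudes are in the acquisition device's arbitrary
pressure units.  This model guarantees that the A–G landmark structure
exists and is the simplest one that does.

**Calibration.**  For each class the main wave's amplitude, centre and
falling-flank width, and the mean period, are tuned by
`scripts/calibrate_profiles.py` so that the package's *own* feature
extractor recovers the published per-class means of h₁, k, w and w/T
(reference values are stored with each profile in
`pulse_dssn._profiles`).  The calibration runs in two stages: a fixed-point
iteration on the noise-free mean-parameter cycle, then a bias-removal
stage against ensembles of jittered cycles (the width at two-thirds height
is convex in the width jitter, so ensemble means sit above mean-parameter
values by a few percent).  Tidal and dicrotic parameters are not
constrained by the reference table; they were chosen once for plausible
morphology — clearly separated bumps so the notch is detectable — and are
not tuned further.  The calibration is deterministic; `--check` verifies
the shipped constants.

**Population variability.**  Per-record draws: amplitude scale (CV set per
class from the reference h₁ coefficient of variation, 0.24–0.39), main-wave
width scale (CV 0.13, truncated at ±2.5 SD), tidal and dicrotic prominence
(CV 0.12/0.15) and position (SD 0.02 cycle fractions), and a record-level
mean period (CV 0.06).  Within a record, cycle periods jitter with SD 4%
of the mean (truncated normal, ±3 SD).  Measurement disturbances are
additive white noise (default SD 5 signal units, i.e. ~1% of a typical
h₁) and sinusoidal baseline wander (default amplitude 50 at 0.3 Hz).
k inherits the amplitude CV because k = h₁/t₁ and t₁ is amplitude-invariant,
matching the reference table, where each class's k and h₁ CVs nearly
coincide.

**What the simulator does not emulate:** respiratory modulation, motion
artifacts, sensor nonlinearity, beat-to-beat morphology correlation beyond
the shared record-level draw, and arrhythmic cycles.  Passing tests on
synthetic cohorts therefore demonstrate correctness of the pipeline and
the qualitative behaviour of the ensemble, not clinical performance.
About 0.5–1% of simulated records draw a morphology whose dicrotic notch
is genuinely unresolvable (as happens in clinical acquisition); the
pipeline drops them, mirroring the data cleaning reported for the clinical
cohort.

## Preprocessing

* **Denoising** — zero-phase Butterworth band-pass: high-pass 0.5 Hz
  (order 4, applied forward-backward) removes baseline wander; low-pass
  20 Hz removes wideband noise while preserving the pulse band (energy is
  concentrated below 10 Hz).  Zero-phase filtering preserves landmark
  timing; applied twice it changes the output by well under 1% RMS.
* **Segmentation** — the fundamental period is the tallest local maximum
  of the autocorrelation in the 30–200 bpm lag range (the raw argmax can
  sit on the short-lag shoulder produced by wide systolic complexes).
  Upstrokes are prominent maxima of the first derivative of a 15 Hz
  low-passed copy, at least 0.6 periods apart; each onset A is found by
  walking down the ascending limb to the adjacent local minimum.  The
  15 Hz copy is used only for detection; samples are cut from the
  band-passed signal.  First and last partial cycles are discarded.
* **Averaging** — cycles are linearly resampled to the median cycle length
  and averaged pointwise; the output period is the median period.
* **Fixed length** — the averaged cycle is linearly resampled to 800
  samples and min-max normalised to [0, 1] per cycle (a constant cycle
  maps to zeros).  This is the CNN and wavelet input; the choice of
  per-cycle min-max scaling is recorded in configuration.

## Time-domain features

The landmark detector takes B as the global maximum (required in the first
half of the cycle), F as the last local maximum after B with prominence
above 2% of h₁ (retried at lower prominence before failing), E as the
deepest sample between F and the preceding prominent maximum (or B), and
C/D as the extremum pair between B and E, falling back to second-derivative
inflection points when the tidal wave is only a shoulder, then to thirds of
the B–E span.  A cycle without any post-B maximum raises a
"no dicrotic notch" error.

Conventions the clinical literature leaves open, fixed here:

* amplitudes are baseline-relative (minus the amplitude at A, the pulse
  foot);
* **k** = h₁ / t₁ with t₁ expressed in sample intervals at the native
  sampling rate (equivalently h₁/(t₁·f_s)); at 720 Hz this matches the
  numeric scale of the published per-class k statistics, which an
  amplitude-per-second convention does not;
* **w** (one-third pulse width) = width of the main wave at 2/3·h₁ above
  baseline (one third down from the crest), with linear interpolation at
  the crossings;
* **A_s**/**A_d** = trapezoidal integrals of the baseline-relative
  waveform over [A, E] and [E, G]: the dicrotic notch is the
  systole/diastole boundary.

The 23-vector order is: k, A_s, A_d, h₁–h₅, w, t₁–t₅, T, then the eight
ratios t₁/T, t₁/t₄, t₅/t₄, w/T, h₂/h₁, h₄/h₁, h₅/h₁, A_s/A_d.

Numerical notes: scale equivariance is exact to float precision; under
resampling, landmark positions found by discrete peak detection carry a
one-sample tie ambiguity, and the areas change by one trapezoid segment at
the cycle end, so those quantities are equivariant to ~10⁻³ rather than
10⁻⁹.

## Wavelet-packet energies

Full wavelet-packet tree, sym8, 8 levels, periodic boundary extension,
terminal nodes in ascending-frequency (Gray-code) order so band index maps
monotonically to Hz (band width f_s/2/256 = 1.41 Hz at 720 Hz).  The input
is zero-padded to the next multiple of 2⁸ (800 → 1024): zero-padding
preserves signal energy exactly, and with even halving at every level the
transform stays orthogonal, so Σ_j E_j equals the signal energy to machine
precision.  Without padding, odd-length levels break orthogonality and the
energy error reaches tens of percent.  Energies are raw sums of squares; a
relative-energy switch (E_j/ΣE) exists but is off by default.

## Classifiers

* **SVMs** — scikit-learn `SVC`, RBF kernel, C = 2.0, γ = 3.0, with
  pairwise-coupling probability calibration.  Features are min-max scaled
  to [0, 1] (fit on the training split) inside the pipeline; on raw
  feature scales (h₁ ≈ 600) this γ would make the kernel matrix
  numerically diagonal.  A grid search over C ∈ {1..50} (step 1) and
  γ ∈ {1..50} (step 0.5) — 4950 candidates — can be enabled to reproduce
  the published search protocol; the fixed values are the default.
* **1-D CNN** — conv 5×11 → ReLU → pool 2 → conv 25×9 → ReLU → pool 2 →
  conv 100×10 → ReLU → pool 2 → dropout 0.5 → dense 7 + softmax
  (He initialisation; valid padding; the pooling/activation placement is
  a package choice recorded in configuration).  Flattened size 100×92.
* **FCNN meta-learner** — dense 1024 → 1024 → 512 → 7 on the 21
  concatenated base probabilities (order: time-SVM, wavelet-SVM, CNN).
* **Training** — cross-entropy, SGD with momentum 0.9, weight decay 10⁻⁴,
  lr 0.001, batch 8 (CNN) / 32 (FCNN), at most 1000 epochs, early stopping
  when validation loss has not decreased for 10 epochs, best-loss weights
  restored.  All networks are implemented in numpy (float32) inside the
  package; every fit is bit-reproducible from its seed.

## Stacking and leakage control

Data are split 6:2:2 stratified by class.  Meta-learner training inputs
are out-of-fold predictions from a stratified 5-fold within the training
split; base learners are refit on the full training split for inference;
the validation split serves only for early stopping (and grid search when
enabled); the test split is touched once.  SMOTE, when enabled, runs
inside the training split only, in "upstream-once" mode: interpolation in
(raw 800-sample cycle, period) space, after which all three
representations of a synthetic sample are derived from its synthetic
cycle — keeping the three branches consistent.  Whether balancing happened
before or after splitting in the reference protocol is not documented;
splitting first is the leakage-safe choice and will generally produce more
conservative accuracies.

## Benchmark sizing

The calibrated benchmark uses 200 records per class with 15 s records
(≈16–20 cycles each, enough for the cycle average to converge) and caps
CNN training at 60 epochs — early stopping usually triggers around epoch
30–40 at this sample size.  On one CPU the full benchmark (simulation,
preprocessing, 6 CNN fits for out-of-fold stacking plus the final refit,
two SVM branches, meta-learner) takes about five minutes.  Under these
conditions the time-domain SVM and the CNN score in the low-to-mid 0.7s
(test macro-accuracy), the wavelet SVM somewhat lower (band energies of
the smooth synthetic cycles carry less class information than clinical
waveforms), and the stacked model matches or beats the best base
learner — the qualitative ordering the method is designed to show.  (When
one base learner is far ahead of the others the meta-learner essentially
reproduces it; fusion gains are largest when the learners are comparable
and disagree.)

## Known limitations

* The simulator constrains only the four published feature statistics;
  the remaining 19 feature distributions follow from the waveform model
  and are not validated against clinical data.
* Absolute accuracies on synthetic cohorts are not comparable to
  published clinical accuracies; only structural properties (dimensions,
  conservation laws, dominance ordering) transfer.
* The wavelet-SVM branch underperforms its clinical counterpart on
  synthetic data (see above); the stacking conclusion is insensitive to
  this, but per-branch numbers are not calibrated.
* C/D detection on cycles whose tidal wave is a pure shoulder relies on
  inflection points of a smoothed second derivative, which is sensitive to
  residual noise at very low SNR.
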