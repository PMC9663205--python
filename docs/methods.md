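# Methods

This note records the models, estimators and design choices behind
`gaitlfp`, in the order the pipeline runs them, together with the
assumptions a user should know before trusting results on real recordings.

## Synthetic walking sessions

The generator emulates the *structure* of an overground-walking recording
session, not its biophysics.

**Gait timeline.** Cycle durations are i.i.d. normal (default mean 1.1 s,
SD 0.05 s, truncated at 30% of the mean — values typical of comfortable
adult walking). Within a cycle of duration *d*, events sit at fixed
fractions: RTO at `double_support_fraction·d` (default 0.1), RHS at
`0.5·d`, LTO at `(0.5 + double_support_fraction)·d`. Turns are declared
intervals, not simulated kinematics; cycles overlapping them are flagged.

**Foot sensors.** FSR channels are piecewise-linear load curves per stance:
the heel (calcaneus, 5MT delayed 20 ms) loads over 40 ms with the 5%-of-max
crossing placed exactly at heel-strike, and unloads mid-stance; the toe
(hallux, 1MT leading 30 ms) loads mid-stance and unloads over 80 ms with
the downward 5% crossing exactly at toe-off. Boundary stances (standing
before the first toe-off, after the last heel-strike) are included so every
planted event produces a crossing. Ankle angular velocity
(plantarflexion-positive) is a raised-cosine burst peaking at toe-off plus
a fast braking transient at heel-strike. Additive Gaussian noise is
specified as a force fraction (default 0.01).

**Field potentials.** Background is Gaussian `1/f^β` noise via spectral
shaping (β default 1.5, RMS default 10 µV — the source recordings never
characterize baseline spectra, so these are calibration choices, not
claims). Band-limited components are 4th-order zero-phase Butterworth
filtered white noise, not sinusoids, so coherence and wavelet estimators
see realistic bandwidth. A component's RMS is `snr` times the background
RMS inside its band; the default `snr = 2.5` puts the baseline spectral
peak roughly 7× above the 1/f floor, comparable to a prominent subthalamic
narrowband peak. Gait gating multiplies the component envelope by
`1 + gain` inside a percent-cycle window, with raised-cosine ramps of 5%
cycle width; `gain = 0` leaves the channel exactly stationary.
`mirror_modulation` shifts a window by +50% (splitting it when it wraps) to
build the opposite hemisphere. Coherent pairs share a gated band-limited
component weighted `sqrt(mixing)` against independent same-band noise
weighted `sqrt(1 - mixing)`.

The canonical planted scenario (`gaitlfp.scenarios`) uses a 6–12 Hz
component with window 0–35% of the left-anchored cycle on the left
channel — weight acceptance through contralateral mid-swing — mirrored to
50–85% on the right. The window length matters: the per-event power
estimate of a burst of duration *T* and bandwidth *B* carries only ~*BT*
degrees of freedom, so very short windows (say 10% of a cycle) make even a
large planted gain statistically invisible at the single-event level.
0–35% (~0.4 s) is both physiologically sensible and long enough that a
gain-1.5 plant is recoverable.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: movement and EMG artifacts, cable noise,
clock *drift* (only constant offset), freezing-of-gait or other
pathological gait dynamics, volume conduction between channels, and
non-Gaussian background statistics. Seeds: one master seed, per-channel
child seeds from `numpy.random.SeedSequence`; identical seeds give
bit-identical bundles.

## Synchronization

Constant clock offset only, matching a short (~2 min) walking bout. Both
accelerometer channels are rectified, low-passed at 5 Hz, mean-removed,
resampled to the coarser rate (64 Hz for the implant), and fully
cross-correlated; the normalized peak is refined by parabolic
interpolation, without which 64 Hz quantization dominates the error. A
normalized peak correlation below 0.5 raises `AlignmentError` rather than
guessing. Measured recovery error on planted offsets spanning ±10 s is
under 1 ms, comfortably within half the coarse sample period.

## Event detection

The 5% threshold is referred to the normalized per-channel range: baseline
= 5th percentile, scale = 99.5th percentile minus baseline, clipped to
[0, 1.05]; this makes detection invariant to the affine calibration of
uncalibrated FSRs. Two-channel OR logic uses an 80 ms merge window —
heel-strike keeps the earlier crossing (first contact), toe-off the later
(last unloading) — and a 200 ms chained refractory period. A crossing must
additionally *come from* the opposite load state (≤ 0.5× threshold before a
strike, ≥ 4× threshold before a toe-off, within 0.3 s) and *confirm* the new
state within 0.1 s; without this, sensor noise riding slow loading ramps
produces spurious opposite-direction crossings. "Ankle velocity impulse"
for IMU heel-strikes is operationalized as the peak |dv/dt| between
toe-offs (strategy-switchable; it is one plausible reading of an
underspecified definition). Default cycle duration bounds are 0.6–2.5 s.

## Spectral estimation and cycle normalization

**CWT.** Analytic Morlet with ω₀ = 6, computed by FFT with unit-energy
scale normalization, so white noise of variance σ² has flat expected
scalogram power σ² at every frequency (verified to within Monte-Carlo error
in tests). Cone-of-influence tiles (within √2·s of an edge) are flagged and
excluded from z-score populations and averages. The wavelet core is
implemented here rather than through a wavelet package because the
coherence estimator needs cross- and auto-spectra under one consistent
scale normalization.

**STFT.** `scipy.signal.spectrogram`, Hann window of 1 s, 90% overlap,
512-point transform (bin width fs/512 ≈ 0.977 Hz, hop 0.1 s at 500 Hz) —
the decomposition style of the implanted device's on-board classifier. The
DC row is dropped.

**Wavelet coherence.** Smoothing is a Gaussian in time with standard
deviation 1.5 wavelet periods per frequency plus a 3-scale boxcar.
Unsmoothed wavelet coherence is identically 1; with this span the
independent-white-noise floor measures ≈ 0.28 (a 1-period span leaves it at
0.37, too high to separate genuine in-band coupling from the floor, which
is why 1.5 periods is the default). Note the floor rises for strongly
narrowband signals, whose correlation time exceeds the smoothing span —
compare conditions against a matched null, as the tests do.

**Cycle normalization.** Per frequency row, z-scoring uses the mean and SD
over all frames of the walking span, excluding declared turn intervals and
COI-flagged tiles ("entire walking period" leaves turns unaddressed; the
exclusion is configurable). Cycles are then interpolated linearly onto 100
equal-duration bins (bin k covering [k, k+1)%, LHS at 0%), z-scored maps
first, averaging second. Grand averages are unweighted across subjects.

## Mixed-model significance mask

Per (frequency, bin) tile the model is `z ~ μ + b_subject + ε` with
`b ~ N(0, σ_b²)`, fitted by REML. Because thousands of tiles are fitted, the
implementation profiles σ_e² and optimizes the single variance ratio
λ = σ_b²/σ_e² from per-subject sufficient statistics rather than calling a
general mixed-model routine; it reproduces `lmerTest` (R) estimates, SEs,
Satterthwaite df and p-values to ~1e-6 on unbalanced data (asserted in the
test suite). The fixed intercept is F-tested against zero — departure of
that tile from the whole-walk average — with Satterthwaite denominator df
from the delta method on the REML information. At the boundary σ̂_b² = 0 the
test reduces exactly to the classical one-sample F over all N observations
(df N−1); with balanced subjects and positive σ̂_b² the df approaches m−1.
The "single fixed effect" reading (intercept departure, per tile) was
chosen over a categorical gait-bin fixed effect; the latter would test a
different hypothesis (any bin differing from any other) and not yield a
per-tile mask. Null calibration measures 4–5% rejections at α = 0.05 over
independent tiles.

## Band scan

Elementary grid 1 Hz over 0–50 Hz (1275 bands) for the biomarker scan;
59 bins over 2.5–50 Hz (1770 bands) for the decoder, the bin count fixed by
requiring n(n+1)/2 = 1770. Event-locked power is read at the frame whose
center is nearest the event (earlier frame on ties; events beyond half a
hop of any frame are dropped with a warning), with band values computed
from elementary-bin cumulative sums. The omnibus is the tie-corrected
Kruskal–Wallis H over the four event classes; the post hoc is a
Nemenyi-style procedure — pairwise differences of mean joint ranks against
the studentized range at k = 4 — i.e. a Tukey-HSD adjustment on rank means,
consistent with the nonparametric omnibus (a raw-value Tukey HSD is
available as `posthoc="tukey-raw"`). A band is flagged significant when any
adjusted pairwise p < 0.05; the omnibus p is reported but does not gate.
No correction is applied across candidate bands — the scan is exploratory
by construction — and the number of bands tested is recorded so users can
post-filter. Shapiro–Wilk and Levene diagnostics are reported alongside,
never as gates. The degenerate all-identical case returns H = 0, p = 1.

## Decoder

Features are instantaneous *log* power (power is χ²-skewed; the
discriminant assumes roughly Gaussian classes, and dB-scale band power is
the conventional feature space) or raw coherence in [0, 1], at toe-off
events, over all candidate bands. The evaluation protocol is strictly
train-first: one stratified 75/25 split; column standardization, forest
tuning (stratified 10-fold CV over a candidate grid, ties to the smallest
pair), fitting, and out-of-bag permutation importance all see training rows
only; the top 10 features (ties broken toward lower, then narrower bands)
feed the LDA; accuracy and ROC AUC come from the held-out 25%.

OOB permutation importance is ranger-style — per tree, the accuracy drop on
that tree's out-of-bag rows when one feature's values are permuted,
averaged over trees — implemented as a numba kernel over the forest's
exported node arrays (scikit-learn exposes no OOB permutation importance);
a tree contributes only for features it actually splits on, which is exact
and makes 1770 features tractable.

The permutation null re-runs the *entire* split-standardize-select-train
pipeline on label-permuted data with a fresh stratified split per
permutation (permuting after selection would inherit selection bias), with
`p = (1 + #{perm ≥ obs})/(n_perms + 1)`, so p is never below its achievable
floor. Hyperparameters are tuned once on the observed labels and held fixed
across permutations. Classes are near-balanced by construction (alternating
gait), so plain accuracy is reported. Default tuning grid:
n_trees ∈ {100, 300, 500, 1000}, features-per-split ∈ {√p, p/3, p/10}.

## Problem sizes used by the tests and reproduction script

Calibration and recovery runs use sizes chosen to make Monte-Carlo
intervals tight while keeping a single-core run short: 500 cycles for
event-detection round trips, 50 planted offsets for synchronization, 1000
independent tiles for the mixed-model null, 1000 replicate scans on a
reduced 3-bin grid (plus 200 planted-separation replicates), 100 random
instances for the rank-statistic oracle, one 100-cycle subject with 200
permutations for planted-signal decoding, and twenty 60-cycle null
subjects on a reduced 10-bin grid with 99 permutations each for decoder
calibration.

## Known limitations

- Constant-offset synchronization only; clock drift is out of scope.
- The mixed-model mask treats tiles independently; no cluster-based or
  other spatial multiplicity correction over the time–frequency plane.
- Satterthwaite inference with very few subjects (here 3) is approximate
  and mildly anticonservative when between-subject variance is substantial.
- The scan's per-band significance is uncorrected across thousands of
  overlapping candidate bands by design.
- Synthetic validation bounds what can be claimed about real recordings;
  see the generator's non-goals above.
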