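# gaitlfp

Gait-cycle-resolved spectral analysis and decoding of cortico-subthalamic
field potentials recorded during overground walking.

Chronically implanted deep-brain-stimulation systems can stream local field
potentials (LFPs) from the subthalamic nucleus (STN) and from subdural
paddles over primary motor (M1) and somatosensory (S1) cortex while a
person walks. Alongside wearable sensors — force-sensitive resistors (FSRs)
under the foot and ankle inertial sensors — such recordings let one ask how
basal-ganglia and cortical oscillations are organized around the gait
cycle, and whether band-limited power or STN–cortex coherence can decode
gait events well enough to drive adaptive stimulation. `gaitlfp` implements
that full analysis chain as a tested, reusable library with a synthetic-data
generator, so every stage can be validated end to end without any patient
data.

## What it computes

Writing the gait cycle as the interval between consecutive left
heel-strikes (LHS at 0%, with right toe-off RTO, right heel-strike RHS and
left toe-off LTO inside it), the pipeline is:

1. **Synchronization** — the neural and kinematic systems run on separate
   clocks; a constant offset is estimated by cross-correlating the
   rectified, low-passed envelopes of the synchronization taps recorded on
   both accelerometers (64 Hz on the implant), with parabolic sub-sample
   refinement.
2. **Gait events** — heel-strike when the calcaneus *or* 5th-metatarsal FSR
   crosses a 5% threshold upward; toe-off when the hallux *or*
   1st-metatarsal FSR crosses it downward; an IMU route uses peak
   plantarflexion velocity (toe-off) and the velocity impulse
   (heel-strike). Cycles overlapping turns, outside duration bounds, or
   violating LHS < RTO < RHS < LTO ordering are excluded.
3. **Cycle-normalized maps** — analytic Morlet CWT (ω₀ = 6) or a 1 s / 90%
   overlap / 512-point Hann spectrogram; wavelet coherence
   `C² = |S(W_a W_b*)|² / (S|W_a|² · S|W_b|²)` from smoothed cross-spectra.
   Each frequency row is z-scored against the entire walking period, every
   cycle resampled onto 100 percent-cycle bins, and cycles (then subjects)
   averaged.
4. **Significance masks** — per (frequency, bin) tile, a repeated-measures
   mixed model `z ~ 1 + (1 | subject)` fitted by REML over per-cycle
   values, F-tested with Satterthwaite degrees of freedom.
5. **Biomarker scan** — all contiguous bands on an elementary grid
   (n bins → n(n+1)/2 bands; 0–50 Hz by default), Kruskal–Wallis across the
   four event classes on event-locked power, Tukey-HSD-adjusted pairwise
   rank comparisons; a band is *gait-event-modulated* when any adjusted
   pairwise p < 0.05.
6. **Decoding** — instantaneous band power (or coherence) at toe-off events
   over all 1770 bands of the 59-bin 2.5–50 Hz grid; features standardized
   with training statistics; a random forest (tuned by stratified 10-fold
   CV) ranks them by out-of-bag permutation importance; the top 10 feed a
   linear discriminant evaluated on a held-out 25% split (accuracy, ROC
   AUC), with significance from re-running the whole pipeline under label
   permutation: `p = (1 + #{perm ≥ obs}) / (n_perms + 1)`.

The synthetic generator produces jittered gait timelines, FSR/ankle-velocity
traces whose threshold crossings land on the planted events, 1/f-background
LFPs with gait-phase-gated band-limited components (lateralized and mirrored
by half a cycle between hemispheres), coherent channel pairs, and planted
clock offsets with tap pulses — all bit-reproducible under a master seed.

## Worked example

Decode left vs right toe-off from one synthetic hemisphere carrying a
6–12 Hz modulation (envelope gain 1.5) during weight acceptance through
contralateral mid-swing:

```python
from gaitlfp import (GaitTimelineSpec, ModulationSpec, simulate_timeline,
                     simulate_lfp, stft_spectrogram, decode_toe_offs)
from gaitlfp.synth import mirror_modulation

timeline = simulate_timeline(GaitTimelineSpec(n_cycles=100, seed=0))
left = ModulationSpec("stn_l", band_lo=6.0, band_hi=12.0,
                      phase_window=(0.0, 35.0), gain=1.5)
mods = [left] + mirror_modulation(left, channel="stn_r")
neural = simulate_lfp(timeline, mods, seed=1)

toe_offs = [e for e in timeline.events if e.kind in ("LTO", "RTO")]
report = decode_toe_offs(
    stft_spectrogram(neural["stn_l"]), toe_offs,
    candidates={"n_trees": (100, 300), "features_per_split": ("sqrt",)},
    n_perms=200, seed=0)
```

which prints, via the fields of `report`:

```
held-out accuracy : 0.760
ROC AUC           : 0.846
permutation p     : 0.0050 (200 permutations)
tuned forest      : (300, 'sqrt')
top bands (Hz)    : 4.9-13.8, 4.9-14.6, 4.9-13.0, 5.7-11.4, 4.1-13.8
```

The selected bands straddle the planted 6–12 Hz modulation, the held-out
accuracy is far above the 0.5 chance level for balanced left/right toe-offs,
and the label-permutation p-value is at its achievable floor for 200
permutations — the decoder found the planted lateralized rhythm.

The same stages are scriptable from the shell:

```bash
gaitlfp run-all --out results/demo --seed 3
gaitlfp report --out results/demo
```

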