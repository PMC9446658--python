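# Methods

This note documents the models, the numerical choices, and the places
where the design was genuinely open.  Nothing here states a result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic sessions

A calibration session is six runs, one per class pairing (LR, FR, LF, LX,
FX, XR), with 90 s rest gaps, a 10 s lead-in and a 5 s lead-out.  Every
trial is 8 s: a 2 s cue pause then a 6 s task.  Each run has equal
per-class trial counts in seeded shuffled order, so a 30-trial run spans
240 s and a 60-trial run 480 s; pooling same-class trials across the six
runs gives 1.5 × (trials/run) trials per class (45–90 for the standard
run sizes).

The EEG model is a sum of two seeded processes, per channel, in µV at
250 Hz on a 32-channel 10/20 montage:

* **Background**: 1/f pink noise (power exponent α = 1, default RMS
  10 µV), independent per channel.  Chosen because it has a realistic
  falling spectrum while keeping band powers analytically predictable.
* **Sensorimotor rhythms**: narrow-band Gaussian noise oscillators, one
  per (channel group × band), shared by the channels of the group.
  Defaults: 8–12 Hz at 6 µV RMS and 18–28 Hz at 4 µV RMS over the three
  sensorimotor groups — right hemisphere {C4, CP4, FC4} (suppressed by
  left-hand imagery), left hemisphere {C3, CP3, FC3} (right-hand), midline
  {Cz, CPz, FCz} (feet).  This is the standard contralateral mapping.

ERD is multiplicative: during the task window of a trial whose class maps
to a group, that group's oscillation amplitude is scaled by
`1 − erd_depth`, starting `erd_latency_s` (default 0.4 s) after the task
cue and ending at trial end.  Relax trials and all pauses keep baseline
amplitude, so the only class information is a task-locked band-power
decrease, as in real sensorimotor EEG.  `erd_depth = 0.5` is the standard
"strong, trained pilot" condition; `erd_depth = 0` is the null condition
used as the chance-level control.

What the generator deliberately does **not** emulate: eye/muscle
artifacts, electrode drift and re-referencing effects, inter-session
non-stationarity, volume-conduction mixing beyond the discrete channel
groups, and amplitude non-Gaussianity.  Tests passing on this data
therefore validate the pipeline's mechanics and sensitivity, not its
robustness to real-world EEG nuisance structure.

Fixtures are written as 16-bit EDF (physical range ±200 µV, 1 s records;
quantization step ≈ 0.006 µV) plus a CSV event table and a JSON schedule
manifest.  The EDF writer/reader is a deliberately small, self-contained
implementation of the classic format; the suite cross-checks it against
an independent EDF reader.

## Preprocessing

Band-pass filters are windowed-sinc FIRs (Kaiser window sized for 60 dB
stop-band attenuation with a 2 Hz transition, odd length).  Offline the
symmetric kernel is applied centred (exact zero phase), so the four band
outputs and the epoch time axis stay aligned; a causal variant
(`zero_phase=False`) reproduces the latency an online system would see.
Decimation 250 → 125 Hz is plain sample dropping — the filter bank has
already confined content below 40 Hz, far under the 62.5 Hz Nyquist limit.

Epochs span −2…+8 s around the cue-pause onset (task onset at +2 s,
index 500 at 125 Hz) on a 21-channel fronto-central/parietal subset.  The
exact 21-channel set is a package choice (the montage rows F, FC, C, CP,
P, PO over the motor strip) and is configurable.  Trials with
insufficient pre/post context are skipped with a warning and counted.

## FBCSP + MI + RLDA

* **Covariance**: per-trial spatial covariance on the +2.4…+8 s task
  samples, trace-normalized, averaged within class.  Trace normalization
  equalizes per-trial broadband power (the field-standard estimate); it
  costs exact invariance to joint channel rescaling, which the raw
  covariance option (`normalize=None`) restores.
* **CSP**: generalized eigendecomposition of (Σ₁, Σ₁+Σ₂); three filter
  pairs per band, rows ordered by descending class-1 variance fraction.
  A rank-deficient composite covariance gets a small ridge with a warning.
* **Log-variance features**: 1 s trailing window, 40 ms step; window
  end-points −1…+8 s → 226 frames at 25 Hz.  Zero-variance windows clamp
  to log(1e−12).
* **Mutual information**: each feature is quantized into 8 equal-frequency
  bins per frame; MI with the binary label comes from the joint histogram.
  Features are ranked by the maximum MI over the task-interval frames
  (`mean` is available); ties break toward the lower feature index for
  reproducibility.  The estimator has the usual positive small-sample
  bias (≈ (bins−1)/(2 n ln 2) bits per frame, inflated by the max over
  frames), which is why small toy datasets show nonzero MI everywhere;
  ranking, not absolute MI, is what the pipeline consumes.
* **RLDA**: Ledoit–Wolf automatic shrinkage of the pooled within-class
  covariance toward scaled identity (a fixed γ ∈ [0, 1] may be given);
  w = Σ̂⁻¹(μ₁−μ₀), bias midway between projected class means (equal
  priors).  Training samples are the per-frame feature vectors of the
  task interval (+2.4…+8 s) of every training trial — the same interval
  that defines the accuracy peak.
* **Cross-validation**: six folds, stratified by class, each fold a
  contiguous-in-time block per class.  Contiguity matters because the
  background rhythms are continuous processes: temporally adjacent trials
  are correlated, and interleaved folds would leak.  CSP, MI ranking, and
  RLDA are refitted from scratch on each training split.  Decoding
  accuracy is the frame-wise correct-rate over held-out trials; the
  feature count k* ∈ {6, 10, 14, 18} maximizes the peak accuracy in
  +2.4…+8 s (ties to the smaller k).
* **TX imbalance**: the task pool T = L∪F∪R is three times the size of X;
  it is randomly subsampled to |X| with a fixed seed before fitting.
* **Cross-session calibration search** enumerates all session subsets of
  sizes 2–4, calibrates on the pooled subset, and scores the held-out
  event-related peak accuracy averaged over classifiers and holdout
  sessions.

## Online command decoder

The four baseline-corrected TSD streams (offset: median over a designated
rest segment — an automated stand-in for the operator's manual zeroing;
scale configurable) pass three gates at 25 Hz:

1. **Agreement**: a class is a candidate when both of its pairwise
   task-vs-task classifiers vote for it and TX is positive (task).  Of
   the 8 sign patterns, 6 have a winner and 2 are cyclic.
2. **Stability**: 300 ms persistence → ceil(0.3 × 25) = 8 consecutive
   frames (the rounding direction is a package choice).  Firing resets
   the streak, so a continuously held candidate re-fires every 8 frames.
   This matters downstream: a command suppressed by the dead-band recurs
   while the pilot sustains the intention, which is what makes the
   dead-band break reachable at all.
3. **Dead-band**: an emission starts a 6 s lockout.  A new stabilized
   event passes early only if ≥ 3 s have elapsed since the emission *and*
   TX has indicated task continuously for ≥ 1 s (the break).  The TX
   streak is tracked on the raw TX sign.  By default the broken-in
   command may repeat the previous one
   (`require_different_after_break=False`): the intended use is
   correcting a wrong command, but nothing in the protocol enforces
   difference.

The safety contract — consecutive emissions ≥ 3 s apart always, ≥ 6 s
apart without a logged break — is checked property-style over seeded
random streams, and the state machine is verified against an independent
step-through reference.

The Triad display maps each pairwise TSD (clipped to ±1) linearly along
its triangle edge toward the favoured vertex and shows the mean of the
three edge points; vertices and edge parameterization are an invented
geometry (only "pairwise outputs on edges, linear composite" is given by
the paradigm).  The composite ball is green in the task state by default;
the convention is configurable.

## Race simulation

The track is 500 m against a 240 s limit.  Default random tracks draw
zone traverse times uniformly from 6.5–7.5 s at the no-command speed and
rescale to the exact total, keeping every zone inside the nominal 6–8 s
zone duration; that yields ~29 zones with all four types present.  Speeds
are not published for the real game; the defaults v_correct = 4.0,
v_none = 2.5, v_wrong = 1.5 m/s are chosen so a perfect run takes 125 s
and a silent run 200 s, bracketing competitive completion times.  An
emitted command stays active until the next emission or the next zone
boundary; in no-input zones every command is wrong and silence yields
v_none.

`closed_loop_eval` steps the decoder and the vehicle together at 25 Hz:
at each frame the synthetic pilot intends the required command of the
zone the vehicle is actually in (after a 1 s reaction latency), driving
the pairwise TSD signs with amplitude `tsd_gain × erd_depth` on top of
smoothed Gaussian noise (TSDs are strongly autocorrelated through the 1 s
log-variance window, so the noise is averaged over 1 s).  At
`erd_depth = 0` the decoder sees pure noise and almost every emitted
command is wrong; performance saturates once the drive exceeds ~3 noise
standard deviations (around `erd_depth ≈ 0.5` at the defaults).

## Analysis

* PSD maps: Welch's method, 2 s Hann segments, 50% overlap, log₁₀
  magnitude sampled at 12–40 Hz in 2 Hz steps, per run, at C3/Cz/C4.
* Band-contribution maps: mean per-frame MI over each band's selected
  features (bands with nothing selected map to zero), optional max
  normalization for plotting.
* Race-time comparison: two-tailed paired-sample t-test on per-position
  differences.  Race times from two periods have no natural pairing, so
  the package pairs by rank order within each group — an explicit,
  documented choice.  Identical groups report t = 0, p = 1; a constant
  nonzero shift has zero-variance differences and is reported as the
  degenerate p → 0 limit with a warning rather than a fabricated finite t.

## Problem sizes

The standard full-size condition is one session of six 40-trial runs
(60 trials per class after pooling, 240 trials total, ≈ 40 min of
synthetic EEG).  The acceptance script runs this condition twice (null
and strong ERD) in about a minute on one CPU.  Unit and property tests
use 8–16-trial runs, which keep the same structure at a few seconds per
session; at those sizes fold noise widens the chance band (tests use
±15% rather than the full-size ±10%) and MI estimator bias is visible,
as noted above.

## Known limitations

* The generator's discrete channel groups make spatial patterns cleaner
  than volume-conducted scalp EEG; CSP performance on this data is an
  upper bound.
* MI is estimated per frame and summarized by the maximum; a pilot whose
  discriminative window is brief but reliable is favoured over one with
  weak sustained separation. The `mean` summary inverts that preference.
* The closed-loop pilot model reacts to zone entry with a fixed latency
  and fixed intention; it does not model fatigue, attention drift, or
  strategy changes within a race.
* The paired race-time test's rank pairing answers "did the distribution
  shift?" rather than pairing physically related races; with n = 10 it
  is a coarse instrument, as any such test would be.
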