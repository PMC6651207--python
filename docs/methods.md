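# Methods

`leansense` studies a question from applied cognitive neuroscience in
manufacturing: do the two classical lean-management problem-solving
routines — KATA (iterate toward a fixed target condition) and (CPD)nA
(Check-Plan-Do-…-Act, directional improvement without a fixed target) —
leave distinguishable signatures in scalp EEG, and can a soft sensor
classify them automatically? The package implements the full chain on
simulated data: a generative model of 14-channel EEG with controlled
inter-channel coupling, causal preprocessing, cross-correlation
hypothesis tests, an image encoding of 1-s segments, and a small
convolutional classifier.

## The coupling model behind the synthetic EEG

Real subject data for this paradigm is not publicly accessible, so the
generator is a first-class, tested component rather than a fixture. It
encodes the neurophysiological structure the analysis is designed to
detect:

- **Executive frontal block.** All pairs among the six frontal sensors
  AF3, F7, F3, AF4, F4, F8 (prefrontal cortex) correlate ≥ 0.45 during
  both routines, with the ventromedial–dorsolateral pairs F7–F3 and
  F4–F8 at ≥ 0.85.
- **Context-dependence switch.** Coupling between the temporoparietal
  sensors (P7, P8) and the frontal pairs is weak under KATA
  (0.21–0.34) and strong under (CPD)nA (0.68–0.73). This is the sole
  class difference and the quantity the classifier must read.
- **Control regime.** Identical frontal block, zero parietal–frontal
  coupling; used as the null for "no hallucinated signal" checks.

Mechanically, channels are linear mixtures of independent unit-variance
Gaussian sources band-limited to 4–30 Hz (the theta–beta range that
carries task-related cortical activity at this sampling rate):

    x_i(t) = Σ_k W[i,k] s_k(t) + σ_i n_i(t) + d_i(t)

With independent unit-variance sources the zero-lag channel correlation
has the closed form

    corr(i,j) = (w_i·w_j) / sqrt((w_i·w_i + σ_i²)(w_j·w_j + σ_j²)),

which is used throughout the tests as an exact oracle for the
generator. The mixing matrix is an explicit factor model — one global
frontal factor, one factor per ventromedial–dorsolateral pair (the
parietal channels load on the paired frontal factors, scaled to the
target coupling), and one background factor for the remaining temporal/
occipital channels — so target correlations are met exactly by
construction. Channel variances are unity; the per-channel noise sd is
whatever variance the factors leave.

Choices that matter:

- **Per-subject jitter.** Each subject-task draws its targets uniformly
  ±0.02 around the regime center, truncated to the *interior* of the
  regime interval (e.g. (CPD)nA parietal targets in [0.70, 0.725]
  inside the 0.68–0.73 regime band). The interior margin exists because
  a 250-s estimate fluctuates ~±0.01 around the analytic value; with
  targets at the band edge, measured coefficients would stray outside
  the regime on a few percent of draws.
- **Noise composition.** 95% of the per-channel noise variance is
  band-limited like the sources (so the 1–50 Hz analysis filters leave
  correlations unchanged) and 5% is broadband white (so the low-pass
  has something real to remove). The closed form above treats both as
  σ_i; the residual bias from filtering the broadband part is < 0.005
  in correlation, far inside the ±0.05 oracle tolerance.
- **Drift.** A random-walk component (sd 2.0 signal units, power
  concentrated far below 1 Hz) is added per channel so that the 1 Hz
  high-pass is doing real work; raw-signal correlations are visibly
  wrong before filtering.
- **Sessions.** 300 s at 128 samples/s; KATA sub-tasks 10/40/250 s
  (KATA-I/II/III), (CPD)nA sub-tasks 10/250/40 s (Check/Plan/Do). The
  generator is stationary across sub-tasks; only the long 250-s windows
  (KATA-III, Plan) are analyzed. Everything is driven by
  `numpy.random.default_rng` streams derived from one cohort seed, so
  recordings are bit-identical across reruns.

What the generator does *not* emulate: eye-blink/EMG artifacts,
electrode drift-outs, non-stationarity across sub-tasks, 1/f broadband
structure, or any demographic covariates. Passing tests therefore show
that the pipeline correctly recovers coupling structure of this model
class — not that the classifier would reach the same accuracy on real
recordings.

## Preprocessing

Causal (forward-only) 5th-order Butterworth filters: high-pass at 1 Hz
(removes DC and drift), low-pass at 50 Hz (removes high-frequency noise
and subsumes a mains notch). Causality is a property test: prepending
zeros must not change later outputs. IIR phase distortion is accepted —
event timing is not analyzed, and zero-lag correlations between
identically filtered channels are unaffected by the common phase
response. Each channel is then rescaled to [0, 1] over the whole
recording (per channel, per recording): amplitude is anonymized while
rank order and inter-channel correlation are preserved. Normalization
happens before segmentation, so segment pixel contrast reflects
whole-session dynamics. Segmentation cuts non-overlapping 1-s windows;
a window straddling a sub-task boundary takes the label at its start
sample; a trailing partial window is dropped.

## Connectivity analysis

The synchrony measure is the normalized zero-lag cross-correlation
(Pearson coefficient of the mean-removed series). A lag-search variant
(maximum-magnitude coefficient over ±max_lag) is exposed but off by
default; coefficients are computed once per pair per task over the full
250-s analysis window, not averaged over segments. The four hypotheses
(H1 frontal block ≥ 0.45; H2 pair channels ≥ 0.85, both on both tasks;
H3 parietal–frontal ≤ 0.34 on KATA; H4 ≥ 0.68 on (CPD)nA) are evaluated
with inclusive comparisons — boundary equality counts as a pass — and
reports carry every per-pair coefficient, not only verdicts.

## Image encoding

Consecutive montage-order channel triplets form pixel rows
([AF3,F7,F3], [FC5,T7,P7], [O1,O2,P8], [T8,FC6,F4], [F8,AF4,∅]); the
last row's empty slot encodes 0. One column per sample gives 5×128 RGB
images for 1-s segments at 128 samples/s. Values are quantized to 8 bits
with round-half-up, making encode→decode exact to 1/255 (property-tested
with random segments). Only KATA-III and Plan segments enter the
classifier dataset: 24 subjects × 2 tasks × 250 segments = 12,000
images, balanced 6,000 per class.

## The soft sensor

Architecture: two convolution blocks (32 then 64 filters, 3×3 kernels,
ReLU, 2×2 max-pooling with the pool height clipped to the remaining
rows), global average pooling over the final feature map, concatenation
with 70 shallow features (per-channel mean, sd, and theta/alpha/beta
band powers from the segment periodogram), a 128-unit ReLU dense layer
and a 2-way softmax — about 37k parameters. Training: Adam at 1e-3,
batch 32, 10 epochs, cross-entropy; the epoch with the best validation
accuracy (earliest on ties) supplies the final weights. One config seed
drives initialization, shuffling and the subject split. The network is
implemented directly on numpy (im2col convolutions, analytic backprop
verified against finite differences in the tests).

Two normalization choices are load-bearing, and both exist because the
class signal is *cross-channel co-movement*, which is amplitude-
invariant, while per-session amplitude profiles are subject
fingerprints:

- each image row-channel is standardized over time at the network
  input;
- shallow features are z-scored within their recording session before
  the merge (session statistics never cross subjects, so subject-level
  train/test separation is untouched), then per-feature on the training
  partition.

Without them, a flatten-based variant of the same network memorizes the
training subjects (training accuracy 1.0, held-out accuracy ≈ 0.54 at
24 subjects); with them, held-out accuracy is ≥ 0.99 across seeds, and
on control-vs-control data (no class signal) it stays at chance —
evidence the sensor reads coupling, not identity. Global average
pooling rather than flatten serves the same end: a correlation
statistic is a time average, and removing position-specific capacity
removes the easiest memorization channel.

Splitting is by subject — 80/10/10, i.e. 20/2/2 at 24 subjects — and
`evaluate` rejects any split in which a test subject also appears in
training, so segment-level leakage is structurally impossible.
Accuracy is reported as ACC = (TP+TN)/(TP+TN+FP+FN) with (CPD)nA as the
positive class, alongside the full confusion matrix.

## Problem sizes and numerical choices

- Study scale is 24 subjects (12,000 images); tests that train the
  classifier repeatedly use 4–8 subject cohorts (2,000–4,000 images),
  which the architecture separates equally cleanly.
- Generator-vs-oracle tolerance ±0.05 entrywise at 250 s; Monte-Carlo
  oracle tolerance 0.02 at 10⁵ samples; encoder round-trip 1/255;
  finite-difference gradient check 5% relative on float32.
- Degenerate inputs are hard errors, not warnings: constant channels
  (normalization), zero-variance series (correlation), cutoffs at or
  above Nyquist, pooling wider than the feature map, sampling-rate
  mismatches on file read (no silent resampling), train/test subject
  overlap.
- Sessions are written as CSV (time column + one column per channel)
  plus a JSON manifest; EDF is read via MNE but not written.

## Known limitations

- The generator's stationarity means sub-task boundaries carry no
  signal; segment labels within a task are interchangeable.
- Zero-lag correlation only; no coherence, phase-locking or directed
  measures, and no group-level statistics across subjects.
- The 99%+ held-out accuracy is a property of the clean synthetic
  regimes; real EEG with artifacts, weaker effect sizes and
  between-subject variability would be materially harder, and the
  shallow-feature branch (inert here by construction) could then carry
  real signal.
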