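# Methods

## Problem and approach

Scalp EEG during an epileptic seizure shows a coordinated, high-amplitude
rhythmic discharge across channels, against a lower-amplitude broadband
interictal background. `topoeeg` detects seizures by measuring how the
*geometry* of a short multichannel window changes: windows are embedded as
point clouds, their multi-scale connectivity and loop structure is
summarized by persistent homology, and the resulting barcode images are
classified. The construction uses all channels jointly — no per-channel
feature extraction or feature stitching.

## Pre-processing

Recordings are reduced to a consistent channel montage (a whitelist, in
whitelist order), band-pass filtered to 0.5–40 Hz and resampled to 256 Hz.
The filter is a zero-phase (forward–backward) 6th-order Butterworth:
zero-phase filtering preserves event timing, which matters because
detection latency is measured in seconds from annotated onset; order 6
keeps a 50 Hz tone below 10% of its input amplitude after the double pass.
Resampling is polyphase with built-in anti-aliasing.

Windows are 2 s, tiled with a stride equal to the window by default. A
window is labeled *seizure* only when fully contained in an annotated
interval; boundary-straddling windows are discarded to avoid label noise.
Interictal candidates must lie at least `interictal_buffer_s` (default
300 s) from every annotated interval, guarding against pre-/post-ictal
contamination, and a seeded uniform subsample of them matches the seizure
window count exactly (balanced classes). Time is seconds from record
start; windows and annotations are half-open intervals.

## Folding construction

A window is an *n* × W matrix (19 × 512 at the defaults). One fold splits
every row at its temporal midpoint and stacks all first halves (in row
order) above all second halves; applied *k* times this yields
*n*·2ᵏ points of dimension W/2ᵏ, conserving *n*·W samples. The stacking
order is fixed for reproducibility but is immaterial to the topology —
persistence is invariant to point order. The default is 3 folds
(152 points for 19 channels), the construction with the richest loop
structure at tractable size; 0–2 folds are available for faster runs.
Distances are Euclidean on the raw microvolt coordinates; an optional
per-channel z-score removes amplitude information when only waveform shape
should matter.

## Persistence engine

The Rips filtration assigns each simplex its diameter as entry scale;
simplices tie-break by (scale, dimension, lexicographic vertex tuple).
Only dimensions 0 and 1 are computed, over Z/2.

* **H₀** — union-find over distance-sorted edges. Every point is born at
  0; a merge at scale d kills one class, so the finite death multiset
  equals the minimum-spanning-tree edge weights (single linkage) and
  exactly one bar per connected component is infinite.
* **H₁** — standard persistence column reduction restricted to the
  triangle block of the boundary matrix, with columns as integer bitmasks
  in the edge basis. A triangle whose reduced column has pivot edge *e*
  kills the cycle born at *e* (zero-length pairs are dropped);
  cycle-creating edges never paired by `eps_max` are reported as infinite
  bars. Reducing the triangle block alone yields exactly the (edge,
  triangle) pairs of the full reduction, because ∂₂ columns live entirely
  in edge rows.

`eps_max` defaults to the cloud diameter (max pairwise distance), which
guarantees final connectivity; a fixed smaller value truncates the
filtration and may leave several infinite H₀ bars. Exact duplicate points
are merged (with a warning) before the filtration, since zero-length bars
are excluded by the birth < death invariant.

Correctness is established in the tests by a second, independent route: an
exhaustive oracle builds the complex explicitly at a single scale and
computes β₀, β₁ as Z/2 boundary ranks by Gaussian elimination. The engine
and the oracle agree on dozens of random small clouds at every critical
scale and midpoint; H₀ deaths are additionally checked against scipy's
minimum spanning tree.

## Barcode images

Barcodes are drawn on a white square raster (default 224×224): H₀ bars
(red) in the top band, H₁ bars (blue) below, sorted by (birth, death) and
spread evenly over the band's rows, 2 px thick, with infinite bars running
to the right edge. The x axis maps [0, x_range] linearly to the width.
Two range policies exist because the choice is genuinely open: a
*per-barcode* range (each image self-normalized, scale-free) and a *fixed*
range shared across segments. The pipeline default is a fixed range equal
to the largest `eps_max` in the dataset, so bar lengths retain amplitude
information — the strongest single cue separating ictal from interictal
windows. Rendering is pure numpy and byte-deterministic.

## Classifier

The default `small_cnn` is a compact convolutional network implemented in
numpy: grayscale inversion and block-averaging to 32×32, two 3×3
convolution + ReLU + 2×2 max-pool stages (8 and 16 filters), and a dense
softmax head, trained with Adam (default learning rate 1e-3, batch 32,
20 epochs; desk-scale runs use ~5 epochs). Under a fixed seed, training
and prediction are bit-reproducible on one CPU. It supports any number of
classes ≥ 2 and trains in seconds at the problem sizes used here.
`googlenet_transfer` (final layer re-initialized to the class count) is
available when the optional torch/torchvision extra is installed; no
pretrained weights are required by any test. Training hyperparameters are
explicit configuration, not tuned claims.

## Evaluation

Segment metrics from confusion counts, as percentages rounded to 2
decimals: Acc, Sens, Spec, Pre, F1 = TP/(TP+0.5(FP+FN))·100, and
mAcc = (Sens+Spec)/2. Zero-denominator metrics are flagged `None` rather
than propagated as NaN; all-zero counts are an error.

*Experiment 1* is a stratified, seeded 70/30 segment split. *Experiment 2*
is leave-one-seizure-event-out: with S events, S models are trained, each
on the other S−1 events' seizure windows plus the interictal windows not
reserved for the held-out fold; the test fold is the held-out event's
windows plus its reserved (round-robin partitioned) interictal windows, so
every fold keeps both classes with no leakage. An event counts as detected
when at least one of its windows is predicted seizure; latency is the
earliest such window's start time minus the annotated onset (0 when the
first in-event window is positive) — windows before onset are tallied as
false positives, never as detections.

## Synthetic data

The generator emulates a 19-channel, 256-Hz scalp recording: per-channel
pink noise (1/f, RMS 20 µV), a 10 Hz alpha component (RMS 10 µV, random
phase), white sensor noise (5 µV), and — inside annotated intervals — a
4 Hz discharge with a half-amplitude second harmonic (a spike-wave-like
sharpness) at 5× the total background RMS, phase-jittered per channel.
Onset is instantaneous, making 0 s detection latency achievable by
construction. Everything is seeded and byte-reproducible.

What it does *not* model: physiological artifacts (EMG, ocular, electrode
pops), inter-subject variability, gradual or focal onsets, channel-specific
seizure topographies, or post-ictal suppression. Passing end-to-end tests
therefore demonstrates that the pipeline's stages compose correctly and
that a strongly separable rhythm change is detected with near-zero
latency — not clinical-grade performance on real recordings.

## Problem sizes and numerical choices

Desk-scale runs use 200 balanced 2-s segments from a 1200-s, 4-event
recording, folded once (38-point clouds), with the compact CNN at 5
epochs; a single 152-point (3-fold) barcode is also computed to validate
the full-size construction. These sizes keep a complete run in the tens of
seconds on one CPU core while exercising every stage at realistic
dimensionality. Numerical details: distances are exact Euclidean;
filtration ties resolve by (scale, dimension, lexicographic vertices);
interval queries use birth ≤ ε < death; EDF quantization error is bounded
by the physical span / 2¹⁶ (sub-0.01 µV at typical amplitudes); latencies
and metrics are rounded to 2 decimals.

## Known limitations

- H₂ and higher homology, sparse/approximate Rips constructions, and
  persistence landscapes/images beyond the raster encoding are out of
  scope.
- The pure-Python reduction is comfortable to ~150 points per cloud
  (seconds); substantially larger clouds would need a compiled core.
- EDF writing produces plain EDF with a sidecar annotation text file;
  EDF+ embedded annotations are read (via MNE) but not written.
- The per-barcode image normalization discards amplitude, which on the
  synthetic task is the dominant class cue; the fixed-range default is
  therefore recommended whenever segments must be compared.
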