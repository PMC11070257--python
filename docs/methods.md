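# Methods

## Problem setting

Passive acoustic monitoring of neotropical katydids must recognize dozens of
species whose calls occupy 7–47 kHz, last from milliseconds to seconds, and
sometimes differ only in inter-pulse interval or centre frequency. Training
material is typically small, imbalanced and domain-mismatched (clean focal
recordings of captive individuals vs noisy field soundscapes). The package
treats detector development as a data-engineering pipeline around a compact
spectrogram CNN: conditioning, soft labelling, augmentation, training,
sliding-window inference with extent-refining post-processing, and
coverage-based evaluation.

## Audio conditioning

Recordings are high-pass filtered (Butterworth, order 12, 6.9 kHz cutoff,
realized as a causal second-order-section cascade — causal rather than
zero-phase to match streaming deployment) and resampled to 96 kHz by
polyphase filtering with built-in anti-aliasing. Continuous audio is cut
into 0.8 s windows; intervals are half-open `[begin, end)` and a trailing
partial window is dropped, because the model requires fixed-shape inputs.
The segment advance (window length minus overlap) is the class-balancing
control: per-class advances between 0.05 and 0.6 s are supported for focal
material, 0.2 s everywhere else. Each retained window is peak-normalized to
[−1, 1] (the normalization rule is per-segment max-abs; all-zero windows
pass through).

## Ground truth

A window's label vector holds one score per detection-target class.
Containment (either direction) scores 1.0; partial overlap scores
`overlap / min(0.8 s, annotation duration)`, so a clipped call is penalized
in proportion to how much of it is missing. Multiple same-class annotations
combine by maximum — a label encodes "how confidently is this class
present", not a count. For classes flagged as short-call (annotations under
0.4 s), focal windows where the (clipped) call lies outside the central
25–75% band and misses the mid-epoch are further scaled by `1 − δ/0.4`,
δ being the distance from the window centre to the nearest clipped call
edge; this teaches lower scores for edge-sitting calls, which sharpens run
boundaries at inference. Background-tagged periods produce all-zero labels;
windows wholly inside background annotations form two pools — background
training windows (0.2 s advance) and "additive background" windows (0.1 s
advance) reserved for the infusion augmentation.

## Augmentation

Six label-preserving, physics-motivated augmentations run inside the
training stream, so every epoch sees fresh variants; timing metadata and
labels are never touched. Time domain: echo (delayed copy at l ∈ [−24, −15]
dB, t ∈ [1, 6] ms), linear volume ramping (l ∈ [0, 6] dB, random end),
background infusion (a real additive-background window, ramped by [0, 9] dB
and scaled to sit [−18, −12] dB below the focal peak), Gaussian noise whose
*realized peak* sits exactly l dB below the signal peak (the draw is
rescaled to hit the target — the level contract, not the SD, is what is
specified and testable; l ∈ [−24, −15] dB focal, [−45, −30] dB non-focal).
Spectral domain: a variable noise floor (the log-conversion constant ε is
drawn so the floor lies in [−105, −85] dBFS; inference fixes −100 dBFS),
and a linear spectral tilt of 0…l dB from the lowest to the highest
retained frequency (l ∈ [−6, −3] dB focal, [−3, 3] dB non-focal).
Application probabilities differ by provenance (echo 0.20 and infusion 0.67
are focal-only; Gaussian noise is 0.75 for non-focal but, for focal inputs,
applies with probability 0.25 only when infusion did not fire; the noise
floor always applies; tilt 0.33 focal / 0.25 non-focal). All draws are
uniform and come from one seeded generator per chain, so a fixed seed
reproduces augmented batches exactly.

## Spectrogram front end

PSD spectrograms use a 480-sample (5 ms) Hann window with 50% overlap and a
transform length equal to the window length — exactly 200 Hz bins and
2.5 ms frames, no zero padding. Rows with bin centres in [6.8, 47.4] kHz
are retained (bins 34–237), so a 0.8 s window always yields a 204 × 319
matrix. The log conversion `10·log10(PSD + ε)` sets the noise floor; with
the default ε = 1e−10 an all-zero window maps to a constant −100 dBFS. No
per-input standardization (mean/variance) is applied; the network instead
applies a *fixed* affine map `(x + 100)/70` to every input — constants of
the architecture, identical for all inputs, carrying no parameters — purely
to condition the optimization.

## Architecture

The classifier is a compact DenseNet-style network: a 3×3/32-filter
pre-convolution; five dense blocks of two composite layers each
(BN → ReLU → 1×1 conv → BN → ReLU → 3×3 conv, growth rate 32, outputs
concatenated onto the block stack); transitions of BN → ReLU → 1×1 conv →
3×3/stride-3 ceil-mode average pooling between blocks; then a final
BN → ReLU, global average pooling, dropout (0.05), a 64-node dense layer
with BN and ReLU, and a 32-node sigmoid output. Ceil-mode pooling takes
204×319 → 68×107 → 23×36 → 8×12 → 3×4.

The block internals are not uniquely determined by the block count, growth
rate and head sizes alone, so the open choices were calibrated against the
parameter budget: with a bottleneck width of 4× the growth rate (128),
transition compression 0.4 (channel counts floored), and biased
convolutions, the default configuration has 470,745 trainable parameters
plus 4,806 non-trainable batch-norm moving statistics — 475,551 in total
(471k / 476k to the nearest thousand). Plain 3×3 blocks without bottleneck
or compression give 536k trainable; the standard 0.5 compression gives
497k; 0.4 is the variant that lands on the budget, and the builder reports
the counts so the calibration is checked in code.

The network is implemented directly over numpy with a small reverse-mode
autodiff (`katydet/_autodiff.py`): convolutions as per-tap BLAS products
(no im2col materialization), batch norm (momentum 0.9 — running statistics
must converge within short runs; ε = 1e−3), ceil-mode average pooling that
never counts padding, and a numerically stable weighted sigmoid
cross-entropy. Gradients are verified against brute-force loops (exact, on
integer-valued inputs) and finite differences in the test suite.

## Training recipe

90% of prepared windows train, 10% validate (uniform split, seeded). The
per-class binary cross-entropy is weighted by inverse class frequency
(frequency = sum of soft scores), normalized to unit mean; a class with no
examples gets weight 0 with a warning. Adam starts at 0.01 and drops ×0.1
at epochs 20/40/50 over 60 epochs, mini-batch 32, dropout 0.05 on the
pooled features. Augmentation chains are provenance-matched per window.
Weight initialization, the split, shuffling, dropout and augmentation all
derive from one integer seed; replicate grids share the initialization seed
across scenarios within a replicate and differ across replicates.

## Inference and post-processing

Test recordings follow the identical conditioning and front end (no
augmentation, −100 dBFS floor) at a fixed 0.2 s advance. For each class,
maximal runs of windows scoring ≥ τ merge into single detections. The
extent rules exploit window-intersection algebra: a lone window reports its
own 0.8 s bounds; runs of 2/3/4 windows report their temporal intersection
(0.6/0.4/0.2 s — 4-window groups are the most-overlapped); longer runs
report the span from the first to the last 4-window most-overlapped period,
`[t₀+0.6, t₀+(k−4)·0.2+0.8]`. All extents are multiples of 0.2 s; the
detection score is the run maximum (peak confidence is what a downstream
threshold should see). An independent brute-force implementation (enumerate
runs, intersect interval lists) backs the grouping in the tests.

## Evaluation

Because detection extents are quantized and one detection can span several
closely spaced calls, matching is by coverage, not assignment: a detection
is a true positive iff summed same-class ground-truth overlap strictly
exceeds 60% of its duration; a call is recalled iff summed same-class
detection overlap is at least 50% of its duration. Recall is the recalled
fraction of ground-truth calls (TP + FN need not equal the call count).
Counts aggregate across files before ratios (micro-averaging), pooled and
per class; precision with no reported detections is *missing*, not zero.
One caveat discovered in testing: recall is not strictly monotone in τ for
arbitrary score tracks — shrinking a run changes its refined extent, which
can overlap a call more (a singleton's 0.8 s extent exceeds any run
intersection). For the bimodal score profiles of a converged detector the
monotonicity holds, and the suite asserts it in that regime.

## Synthetic benchmark

The generator emulates the field problem's structure: calls are trains of
Hann-windowed tonal or linearly swept pulses with template-controlled pulse
duration (≥ 0.8 ms), inter-pulse interval, pulse count, centre frequency
and bandwidth (7–47 kHz). The default three classes place the hardest
discrimination axis first — `pulser_slow` (2 ms pulses, 40 ms intervals)
and `pulser_fast` (2 ms pulses, 15 ms intervals) share a 12 kHz centre
frequency and differ only in interval; `sweeper_high` is a 30 kHz swept
call. Durations sit at 0.366–0.393 s: under 0.4 s so the centralization
penalty is exercised, and long enough that a correct run's refined extent
can satisfy both coverage rules (a 0.2 s four-window intersection covers
≥ 50% of the call, and the call covers > 60% of runs up to six windows —
for much shorter calls the 60% rule fails on any run of 6+, which is the
regime where the field system too reports depressed precision). Durations
also avoid exact multiples of 0.12 s, where a 2-window run's 0.6 s extent
would land precisely on the strict 60% boundary.

Focal files are near-silent with one class each (high SNR); in-situ files
plant calls at 20 dB in-band SNR over pink noise with explicitly annotated
background stretches; test soundscapes plant eight calls per class at
15 dB in-band SNR. Planted calls are separated by at least 0.85 s and stay
0.8 s clear of file edges: calls closer together than one analysis window
merge into a single run whose extent cannot satisfy the 60% coverage rule
even for an ideal detector, and edge calls cannot be covered by a full run
— both would make the benchmark unscorable rather than hard. The in-band SNR contract (call RMS vs noise RMS through
a band-pass at the call's bounds, over the call extent) is realized within
1 dB by construction and asserted in tests. Pink (1/f) noise exercises the
high-pass filter and the noise-floor augmentation realistically. Planted
extents equal the emitted selection-table rows exactly, and a fixed seed
reproduces the corpus byte for byte.

What the benchmark does *not* emulate: reverberation and frequency-
dependent propagation (beyond the tilt augmentation), overlapping calls of
different species, chorus interference, moving sources, or the long-tailed
class imbalance of real assemblages. Passing the scaled-down end-to-end
check therefore demonstrates that the pipeline's machinery — labelling,
augmentation, training, grouping and scoring — is internally consistent and
learnable, not that field-scale accuracy is achieved.

## Desk-scale (reduced) configuration

CPU-only end-to-end runs use the same block family, narrowed: pre-conv 12,
three blocks, growth 12, bottleneck 2×, head 48, and a frequency-only
(6, 1) input pool. Pooling frequency to 1.2 kHz bins (34 rows) keeps cost
down while preserving the 2.5 ms time base — the inter-pulse interval is
the discriminative trait, and pooling time would smear the 1-frame-wide
pulses that carry it. The reduced schedule is 10 epochs, batch 16, learning-
rate drops at epochs 6 and 9, and gradient clipping at global norm 1.0 —
without clipping the short high-rate phase spends most of its epochs on an
optimization plateau. Clipping is a stability device of the desk-scale
schedule only; the full 60-epoch recipe leaves it off. Batch-norm momentum
is 0.9 throughout so running statistics converge within short runs. Problem
sizes for the end-to-end check: six 6 s focal files per class, two 20 s
in-situ files, two 45 s test soundscapes.

## Numerical choices and degenerate inputs

Thresholding is inclusive (score ≥ τ); the 60% TP rule is strict, the 50%
recall rule inclusive, both asserted at exact boundary values. All-zero
audio passes through normalization and produces constant-floor
spectrograms; peak-relative augmentations reject all-zero inputs
(peak-relative scaling is undefined there). Echo delay is drawn
continuously and rounded to whole samples. Transition channel counts are
floored; a configuration that floors to zero channels is rejected at build
time. Detections are emitted in (class, begin-time) order so output files
are reproducible.
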