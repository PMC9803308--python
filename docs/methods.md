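# Methods

## The beat frame

All models operate on fixed 370-sample frames at 250 Hz — one cardiac beat
from a P-wave onset to the next P-wave onset (≈ 1.48 s, comfortably longer
than a beat at normal heart rates). Beats shorter than 370 samples are
completed with exact zeros carrying a dedicated PAD class; beats longer than
370 samples are truncated with a warning (only the padding direction has a
principled completion). Per-sample labels come from half-open
`[onset, offset)` intervals — half-open so no boundary sample carries two
wave labels — over the five classes P, QRS, T, ISO (isoelectric), PAD.
A frame is valid only if PAD labels form a contiguous suffix and the signal
is exactly zero there; this invariant is asserted on every construction.

## Synthetic beat generator

The generator exists to make the pipeline trainable and testable offline
with exact per-sample ground truth. Each beat is a flat isoelectric baseline
plus three Gaussian bumps (P, QRS, T) with amplitudes in normalised [0, 1]
units so the sigmoid output layer of the auto-encoder can represent them
directly. A sample belongs to a wave iff it lies within ±3 widths of that
wave's centre (supports are validated not to overlap); everything else in
the beat is ISO.

The baseline sits at 0.1 (sampler: U(0.05, 0.15)), not at zero. Real
recordings, min-max normalised to [0, 1], place the isoelectric level
strictly inside the interval (the signal's minimum lies below the baseline),
so exact zero is reserved for the padding — without this the trailing ISO
stretch would be indistinguishable from PAD and the frame invariant
"PAD ⇔ zero at the tail" could not hold.

Default morphology ranges (samples at 250 Hz): P amplitude 0.12–0.28,
centre 45–65, width 6–10; QRS amplitude 0.8–1.0, centre 120–140, width 4–6;
T amplitude 0.25–0.5, centre 215–245, width 12–18; beat length 300–370.
These are plausible normal-sinus proportions: a small rounded P, a tall
narrow QRS, a broad medium T.

**Noise injection.** Noise is scaled so the achieved SNR
`10·log10(Σ clean² / Σ noise²)` over the un-padded part equals the target
exactly (the scale factor is closed-form); the PAD suffix is never touched.
Four noise families: white Gaussian (default), baseline wander (a
0.15–0.4 Hz sinusoid with random phase — the respiratory drift band),
powerline (50 Hz sinusoid), and an equal-power mixture. The training
protocol injects at 35 dB; the generator accepts any finite target and is
exercised over [0, 40] dB in the tests. All randomness flows through
explicit seeds; identical seeds give bit-identical datasets.

**Alternans.** `inject_alternans` rescales the T-wave segment of every
even- (or odd-) indexed beat so its peak rises by exactly `delta`, leaving
every non-T sample untouched; the segment deviation above its floor is
scaled, so the wave's edges stay continuous. Noise-free, the even/odd
T-peak difference series then equals ±delta exactly, which is the oracle
the closed-loop tests use.

**What the generator does not emulate:** physiological beat-to-beat
dynamics (no ECGSYN-style model), pathological morphologies beyond T-peak
alternans, biphasic or inverted T-waves, multi-lead recordings, electrode
motion artifacts. Results on this data show that the pipeline's mechanics
are correct and learnable; they do not certify performance on clinical
recordings.

## Denoising auto-encoder

Single hidden layer: y = φ(Wx̃ + b), z = φ′(W′y + b′), with φ = ReLU and
φ′ = sigmoid; trained noisy → clean with Adam on the mean squared
reconstruction error (1/N) Σ ‖xᵢ − zᵢ‖² (sum over the 370 samples, mean
over the batch). Two layouts: 370–185 ("model1", compressing) and 370–370
("model2", full-width). Full-scale defaults: 400 epochs, batch 64, learning
rate 0.00095. Weight initialisation is Glorot-uniform, fixed by seed; the
final partial batch is used, not dropped.

Frames are min-max normalised per frame into [0, 1] using the *noisy*
frame's range (so the constants are available at inference) and
de-normalised on output; reconstruction SNR is therefore reported in the
original units. After decoding, the PAD suffix is reset to exact zero so
frame invariants survive the round trip.

The reconstruction quality metric is the standard power-ratio SNR in dB,
computed per beat over the un-padded samples and averaged across beats
(per-record concatenation is available but the per-beat mean is the
default). A perfect reconstruction reports `inf` rather than raising.

**Desk-scale behaviour.** At the desk scale used throughout
(200 training beats), the held-out reconstruction SNR of the full-width
layout plateaus near 30 dB regardless of training length — the limit is
generalisation from 200 beats over the ~11-dimensional morphology space,
not optimisation. Consequently, with 35 dB input noise, denoising does
*not* raise SNR above the input at this scale (the error the auto-encoder
adds exceeds the tiny noise it removes); the front-end earns its keep at
low SNR and for structured artifacts — at 15 dB input it raises SNR by
≈ 5 dB, and under baseline wander it improves downstream delineation
accuracy (see the pipeline test). The full-width layout consistently
out-reconstructs the compressing one, at every seed tested.

The short-run schedule used in tests and the acceptance script is
50 epochs, batch 8, learning rate 0.005: at 50 epochs the full-scale
schedule (batch 64, lr 0.00095) performs only ~150 Adam steps, far too few
to converge, so the short runs take smaller batches and a standard
short-run Adam rate.

## ConvBiLSTM delineator

Four convolutional stages (8, 16, 32, 64 filters; kernel 3; stride 1;
ReLU), each zero-padded so all stages preserve the 370-sample length — a
per-sample labeler needs one feature vector per input position, which fixes
the padding choice. Then a single bidirectional LSTM layer (standard gated
cell, 64 hidden units per direction, forget-gate bias initialised to 1),
the two directions' hidden states concatenated per position, and an affine
+ softmax head over the five classes. The loss is per-sample categorical
cross-entropy. Argmax ties break to the lowest class index
(deterministic).

Full-scale defaults follow the delineation recipe (300 epochs, batch 8,
lr 1e-5); the desk-scale runs use 30 epochs at lr 1e-3 for the same reason
as above. On 200 synthetic beats this reaches ≈ 98% held-out per-sample
accuracy and ≈ 100% on PAD positions; residual errors sit at wave
onset/offset boundaries, where the Gaussian tails make the exact ±3-width
cutoff genuinely ambiguous.

Onsets/offsets are the first/last index of each contiguous run of a wave
label; runs shorter than 3 samples are discarded as label noise
(configurable). The R-peak is the sample argmax inside the first QRS run.
A ±5-sample (20 ms at 250 Hz) window is the scoring tolerance for derived
boundaries, the conventional delineation tolerance at this sampling rate.

Both networks are plain numpy with hand-written backpropagation; the test
suite checks every parameter's gradient against central finite differences
on a small instance, and the convolution and recurrence against brute-force
sliding-window and symmetry oracles.

## T-wave alternans rule

Given the ordered T-peak amplitudes of a record and its mean heart rate:

1. split peaks into even- and odd-indexed groups (0-based index parity —
   the only reading that pairs alternating beats; swapping the convention
   negates TW and changes nothing observable, which the tests assert);
2. TW = odd − even elementwise, truncated to the shorter group;
3. count zero-crossings of TW: sign changes between consecutive elements,
   with exact zeros transparent (they carry the last nonzero sign). Under
   this convention a one-sided TW series has zero crossings, consistent
   with reference records that report zero crossings alongside a nonzero
   magnitude;
4. alternans is present iff `crossings < 0.35 · len(TW)` and
   `heart rate > 80 BPM`, both strict;
5. magnitude = `max |TW|` over the interior (first and last element
   excluded, as edge effects); records not detected report magnitude 0.

Amplitude units pass through unchanged (microvolts in, microvolts out).
When quantifying a delineated record, the heart rate is
`60·fs / mean(R-R interval)` with R-peaks taken from the delineator; when
evaluating a printed decision table, the printed heart rate is used as-is.
The packaged 30-record reference table (`ecgwaves/data/`) carries the
printed zero-crossing counts, TW lengths, heart rates and verdicts; the
rule reproduces all 30 verdicts (20 detected, 10 non-detected).

The rule's statistical logic: under sustained alternans TW keeps one sign,
so its crossing count is far below 0.35·len; for independent beat-to-beat
jitter the crossing count concentrates near half the length
(Binomial(len−1, ½)), far above the gate, so false detection requires an
unlikely sign run.

## Evaluation

Per-class metrics are one-vs-rest from the 5×5 confusion matrix:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP),
accuracy (TP+TN)/total — per-class accuracy is only meaningful one-vs-rest
— and F1; the summary row is the unweighted mean over all five classes
including PAD. Zero-denominator ratios are NaN, never silently zero, and
NaN propagates into the average. ROC curves use trapezoidal AUC;
precision-recall uses step-wise interpolation (average precision), since
the two differ and the step-wise form does not overestimate saw-tooth PR
curves. Micro and macro averages are both emitted.

## Problem sizes and determinism

Desk scale throughout: 200 training beats, 50 held-out, 50-epoch DAE runs,
30-epoch delineator runs, 128-beat alternans records, 20-seed null sweeps.
Every stochastic step takes an explicit seed; training is bit-reproducible
for a fixed seed. Divergence (non-finite loss) raises an error naming the
epoch rather than returning silently.

## Known limitations

- Full-scale figures obtained on annotated clinical databases with
  hundreds of thousands of beats and full 300–400-epoch training are out of
  reach of the synthetic desk scale, and no claim is made about them.
- The WFDB support is a minimal format-16 reader/writer with a plain-text
  annotation sidecar (ecgpuwave-style symbols); compressed/other signal
  formats and binary annotation files are not handled.
- The delineator assumes pre-segmented beat frames; continuous-strip
  delineation without beat segmentation is out of scope.
- The TWA rule is the zero-crossing decision rule only; spectral and
  modified-moving-average TWA methods are not implemented, and the
  detection thresholds are not clinically calibrated.
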