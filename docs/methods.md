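# Methods

`ecgrpm` implements a five-class arrhythmia classification pipeline for
annotated single-lead ECG: wavelet denoising, beat/window segmentation,
time-series-to-image encoding centered on the relative position matrix
(RPM), and an attention-augmented 18-layer residual classifier. This
note records the model, its assumptions, the defaults, and the design
choices made where the design was genuinely open.

## Signal model and label scheme

Input is a single-lead ECG sampled at `fs` (nominally 360 Hz, the MLII
lead convention of the MIT-BIH Arrhythmia Database), with beat
annotations given as (sample index, symbol) pairs. Annotations are taken
as authoritative: no QRS detection is performed. The default label
scheme retains the five beat symbols N (normal), L (left bundle branch
block), R (right bundle branch block), A (atrial premature contraction)
and V (premature ventricular contraction), mapping each to itself and
discarding every other symbol; the scheme is user-overridable. WFDB
annotation indices are used directly as 0-based offsets into the stored
signal, the package's single internal convention.

## Denoising

The record is decomposed with a db6 discrete wavelet transform to 5
levels (symmetric boundary extension). At 360 Hz the ECG energy sits
almost entirely within the first 4–5 dyadic scales, so 5 levels separate
in-band structure from broadband noise while leaving the low-frequency
approximation untouched. Detail coefficients are shrunk with the
compromise soft–hard threshold

    f(Y) = sign(Y) (|Y| − α λ)   if |Y| ≥ λ,   0 otherwise

with α = 0.5 by default: α = 0 reproduces hard thresholding (retained
coefficients untouched), α = 1 soft thresholding (uniform shrinkage by
λ), and intermediate α trades the bias of soft against the variance of
hard thresholding. The threshold magnitude λ is not part of the
published threshold function, so the package uses the universal
threshold λ = σ̂ √(2 ln N) with σ̂ = median(|d₁|)/0.6745 estimated from
the finest detail level — the standard choice when no oracle threshold
is available. A `threshold_rule="none"` setting forces λ = 0 and makes
the filter an exact identity (used as a round-trip check). Signals
shorter than the wavelet's maximum depth reduce the effective
decomposition level with a logged warning.

Denoising is applied to the whole record before segmentation: filtering
300-sample excerpts separately would incur boundary artifacts on every
beat. A per-segment path exists for comparison via the library API
(`denoise` accepts any 1-D array).

## Segmentation

Single beats: each annotated R peak at index r yields the 300-sample
window [r−99, r+200] (99 samples ≈ 275 ms before the peak, 200 ≈ 555 ms
after at 360 Hz), enough to cover P–QRS–T for a resting heart rate.
Beats whose window crosses a record edge are dropped and counted in the
run log.

Five-second windows: consecutive non-overlapping 1800-sample windows
from sample 0; a window is kept, labeled N, iff it contains at least one
annotation and every annotation inside is normal. This produces the
"mixed" dataset variant that counteracts the normal-class imbalance of
beat-level segmentation; the trailing partial window is discarded.

## Image encoding

Every segment is z-scored (population σ; constant segments map to zeros
with a warning) and, when longer than the target length m, reduced by
piecewise aggregate approximation (block means over frames
[⌊kn/m⌋, ⌊(k+1)n/m⌋)). Five-second windows default to m = 300 so both
segment kinds produce 300×300 matrices; single beats are encoded at
native length. Four encoders are provided:

- **RPM** — M[i,j] = x̃ⱼ − x̃ᵢ. Anti-symmetric with zero diagonal; each
  row redraws the series against one reference time step. Because the
  z-score removes affine transforms of the raw segment, the final image
  is bit-identical under x → ax + b (a > 0).
- **GASF** — the series is min–max rescaled to [−1,1], embedded as
  angles φ = arccos(x), and G[i,j] = cos(φᵢ + φⱼ) (summation field).
- **RP** — binary recurrence |x̃ᵢ − x̃ⱼ| ≤ ε, with ε the 10% quantile of
  off-diagonal distances by default (no published ε exists; a quantile
  adapts to segment scale). Recurrent pairs render black. The
  unthresholded distance map is available via `binarize=False`.
- **MTF** — values are assigned to Q = 8 empirical quantile bins
  (boundary ties go to the lower bin), a row-normalized first-order
  transition matrix W is estimated from consecutive pairs, and
  T[i,j] = W[bin(x̃ᵢ), bin(x̃ⱼ)]. Rows from never-left bins are zero.

Real-valued matrices are min–max scaled to 8-bit gray with half-up
rounding (`⌊255t + 0.5⌋` after dividing by the range first, which pins
the RPM diagonal at exactly 128); degenerate constant matrices map to
zero. Images are single-channel 8-bit; colormapped renderings are
considered visualization only. The gray matrix is bilinearly resampled
to a fixed raster (default 224×224, 64×64 in desk-scale runs).

## Classifier

The network is an 18-layer residual CNN: 7×7/2 stem convolution, 3×3/2
max pool, four stages of two basic blocks (64/128/256/512 channels,
stride 2 between stages), global average pooling and a linear head.
After each stage a channel-attention gate computes per-channel weights
w = sigmoid(W₂ relu(W₁ gap(x))) with bottleneck width C/r (r = 16
default) and fuses them additively, out = x + w⊙x, so each channel is
scaled by 1 + w ∈ (1, 2). Channel-only attention with additive fusion is
implemented exactly as described; a spatial sub-block is deliberately
out of scope. Attention is inserted per stage (4 sites) rather than per
basic block (8), matching the stage-level granularity of the
architecture; the sites are configurable.

The implementation is a self-contained numpy framework (im2col
convolution, batch normalization with running statistics, hand-derived
backward passes, Adam with β₁ = 0.9, β₂ = 0.999). Every layer's backward
pass is verified against float64 central differences in the test suite.
Initialization is He-normal, seeded. Pretrained-backbone initialization
is exposed only as an input-channel convention flag (grayscale
replicated to 3 channels); weights are always freshly initialized — no
weight downloads.

Training: stratified 8:2 train/test split with 20% of the training
portion as validation (all seeded), batch size 32, Adam at learning rate
1e−4, cross-entropy loss, per-epoch history, and best-validation-
accuracy checkpointing. The test split is never touched during training.
Inputs are scaled to [0, 1].

## Evaluation

One-vs-rest TP/FP/FN/TN are derived per class from the K×K confusion
matrix; ACC, PPV, SE, SP and F1 follow the standard formulas, with
division-by-zero cases reported as 0 (SP = 1 for a class never predicted
and never present) with a logged warning. Overall accuracy is
trace/total; "average" PPV/SE/SP are macro (unweighted) means — the
averaging rule was open, and macro reproduces headline-style averages
from per-class rows. ROC curves use softmax scores with thresholds at
the observed score values (delegated to scikit-learn's threshold sweep);
the micro curve pools all (sample, class) decisions, the macro curve
averages per-class curves on the union FPR grid; AUC is trapezoidal. The
threshold-sweep AUC is checked against a Mann–Whitney pair-counting
oracle to 1e−10.

## Synthetic data

The generator emulates an annotated single-lead record at 360 Hz with
five class-distinct beat morphologies built from sums of Gaussian bumps:
N has a P wave, narrow QRS and upright T; L/R have widened, slurred QRS
with discordant repolarization; A resembles N with an inverted P and
flatter T; V is a wide, large biphasic complex without a P wave. Every
template is 300 samples with its R peak exactly at sample 99. Beats are
interleaved at jittered RR spacing (mean 320 samples ≈ 67 bpm, 3%
jitter, clamped so beat windows stay disjoint), with 5% within-class
amplitude/width jitter, 0.3 Hz sinusoidal baseline wander of 0.05 mV,
and additive white noise at 20 dB SNR by default — mild but nonzero
corruption, so the denoiser and encoders face non-trivial input.

What the generator does *not* emulate: rhythm context (compensatory
pauses, bigeminy), inter-patient morphology variability, electrode
artifacts, or class imbalance. The synthetic classes are far more
separable than real MIT-BIH beats, so passing end-to-end tests
demonstrates that the pipeline is implemented correctly and can learn
class structure — not that real-data accuracies are reproduced. Defaults
(50 beats per class) keep desk-scale training tractable.

## Problem sizes and numerical choices

The desk-scale end-to-end run (acceptance script and test suite) uses 50
synthetic beats per class, RPM encoding rendered at 64×64, and 12
training epochs — sizes chosen so a full CPU run completes in minutes
while leaving clear margin over the 0.90 held-out accuracy bar; on this
data validation accuracy saturates at 1.0 around epoch 6–7. Batch-norm
running statistics (momentum 0.1) need several epochs to converge before
eval-mode inference is reliable, which is why very short runs show
chance-level validation accuracy despite perfect training accuracy.
Float32 is used throughout training; gradient tests run the layers in
float64. Gray rounding is half-up; PAA uses block means (not
interpolation); MTF boundary ties go to the lower bin; RP uses ≤ in the
recurrence comparison.

## Known limitations

- No GPU path and no pretrained weights: full-database replication of
  the published headline accuracies is out of scope by design.
- The WFDB reader supports formats 16 and 212, single-record headers,
  and the beat-annotation subset of the MIT annotation code table —
  sufficient for the MIT-BIH arrhythmia records and for round-tripping
  the package's own writer, not a general WFDB implementation.
- The 1-D raw-signal comparison pathway and GAN-based augmentation are
  not implemented.
- `reproduce-counts` emits per-record and total beat/window counts for
  any record set; published per-class totals depend on an unpublished
  38-record selection and so are not exactly recoverable in general.
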