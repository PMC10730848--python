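# Methods

This note records the modelling and numerical choices behind `vesselseg`,
the assumptions they rest on, and what the tests do and do not establish.

## Architecture

Each of the three backbone paths maps a 1-channel image (H, W multiples of
8) through four levels; level *i* lives at resolution H/2^{i−1}. All paths
share the CBR₂ block — two rounds of 3×3 convolution (stride 1, padding 1),
batch normalisation and ReLU — and all decoder features d_i carry the
level's width w_i. Default widths are (64, 128, 256, 512); the test preset
uses (8, 16, 32, 64). There is deliberately no fifth level and no
1024-channel stage: three downsamplings keep the parameter count and
receptive-field growth moderate at fundus resolutions.

**Spatial path (U-Net).** Encoder: CBR₂ then 2×2 max-pool between levels.
Bottleneck d₄ = CBR₂(e₄). Decoder level i: 2×2 stride-2 transposed
convolution (w_{i+1} → w_i), concatenation with the same-level encoder
feature, CBR₂ (2w_i → w_i).

**Boundary path (SegNet).** Same encoder, but each pool records the
row-major argmax position (0..3) of every 2×2 window; ties keep the first
position, which makes the forward pass deterministic. The decoder places
values back at the recorded positions (max-unpooling: all other positions
zero) and applies CBR₂; there is no skip concatenation. Because unpooling
requires its input channels to match the recorded indices' channels (w_i)
while d_{i+1} carries w_{i+1}, a 1×1 convolution adjusts channels
immediately before each unpool. In the original symmetric-VGG SegNet this
adjustment is invisible because widths match; with a width ladder it has to
be explicit.

**Frequency path (Haar).** Encoder: g_i = CBR₂(e_i),
e_{i+1} = Concat[DWT(g_i)] — the orthonormal single-level 2-D Haar analysis
applied per channel, grouped by subband (all LL first, then HL, LH, HH).
One analysis step quarters the pixel count and quadruples channels with no
information loss. Bottleneck d₄ = CBR₂(e₄) (4w₃ → w₄). Decoder level i: a
1×1 convolution maps d_{i+1} (w_{i+1}) to 4w_i, the synthesis transform
(Split + IDWT) restores resolution with exactly w_i channels, and CBR₂
fuses concat(g_i′, g_i) (2w_i → w_i). The 1×1 adjust is the wavelet-domain
analogue of the transposed convolution in the spatial path and keeps the
decoder width schedule uniform across paths.

Haar conventions: per 2×2 block [[a,b],[c,d]], ll = (a+b+c+d)/2,
hl = (−a+b−c+d)/2 (horizontal change), lh = (−a−b+c+d)/2 (vertical),
hh = (a−b−c+d)/2 (diagonal). The orthonormal scaling (1/2 per block) was
chosen over the unnormalised sum/difference form because it conserves
energy — a sharp, testable invariant — and keeps feature magnitudes stable
across levels. Under this convention the subbands map onto PyWavelets'
`dwt2(x, "haar")` as ll=cA, hl=−cV, lh=−cH, hh=cD, which the tests verify.
Odd-sized inputs are a hard error in the wavelet layer; padding is the data
pipeline's job.

**Heads.** The paths couple only here; the encoders exchange no features
(the per-level equations reference only their own path, and nothing else is
specified). Per level, a deep-supervision head is an independent 1×1
convolution (no weight sharing across levels) over the channel-concatenated
decoder bundle, followed by channel softmax; channel 0 is background,
channel 1 vessel, fixed everywhere (labels, metrics, prediction). The
auto-encoder head compresses the concatenated bottleneck features with a
1×1 convolution to w₄ channels, then halves channels at each of three 2×2
stride-2 transposed convolutions (ReLU between), ending in a 1×1
convolution to one channel; its target is the same preprocessed grayscale
tensor fed to the network. u₂..u₄ and X^R exist for training only;
prediction is the vessel channel of u₁.

## Objective

Loss = β·Loss_AE + Σ α_i·Lⁱ(u_i, v_i) with defaults
[β, α₁..α₄] = [0.1, 1, 0.2, 0.2, 0.2]. Choices the formula leaves open:

* Lⁱ is the **mean** (not sum) pixelwise cross-entropy, so the α weighting
  is resolution-independent.
* Level labels v₂..v₄ come from top-left nearest-neighbour 2× subsampling:
  deterministic and binary-preserving. Majority voting was considered and
  rejected as the default (it biases thin vessels away at coarse levels in
  a threshold-dependent way).
* The log argument is clamped at 1e-12 so a saturated softmax yields a
  large finite loss instead of an infinity; the clamp region gets zero
  gradient.

## Training protocol

Defaults reproduce the printed protocol exactly: per-image min-max
normalisation to [0,1]; grayscale X = 0.299R + 0.578G + 0.114B (these
coefficients as printed, including 0.578 for green); geometric augmentation
(identity, horizontal/vertical flip, 90/180/270° rotations, two random
±16 px translations with reflection padding — eight copies per record,
image and labels transformed identically); 4000 random 64×64 patches in
total over the augmented pool; Adam at learning rate 0.0005 (β₁=0.9,
β₂=0.999), batch 64, 50 epochs; constant learning rate, no early stopping,
no validation split (opt-in flag), final-epoch checkpoint. Rotations are
restricted to multiples of 90° by default because they are lossless on
rasters; arbitrary angles exist behind a config flag with nearest-neighbour
label interpolation. Patch sampling ignores the FOV mask by default (an
optional flag restricts patch centres to it). Batch-norm uses momentum 0.1
and eps 1e-5 with standard running-statistics inference.

Inference pads reflectively (bottom/right) to the next multiples of 8 and
crops back, so arbitrary sizes such as 565×584 round-trip exactly.

## Metrics

Dice = 2TP/(2TP+FP+FN), SE = TP/(TP+FN), SP = TN/(FP+TN),
Acc = (TP+TN)/total, positive class vessel, threshold 0.5 with ≥ inclusive.
Set aggregation is micro (counts summed before one division); per-image
rows are retained for macro analysis. A zero-denominator score is reported
as "undefined" and excluded from aggregates, never silently 0 or 1. The
full image is scored by default; `--roi fov` restricts to the
field-of-view mask (conventions differ between published evaluations, so
both are available).

## Numerical engine

With no deep-learning framework as a dependency, the network runs on a
small tape-based reverse-mode autodiff over float64 NumPy arrays.
Convolutions use im2col assembled by k² shifted slice copies plus BLAS
matmuls; the convolution input-gradient is computed as the 'same'
correlation with the channel-transposed, spatially flipped kernel; the 2×2
stride-2 transposed convolution exploits its non-overlapping windows to
reduce to a single matmul plus reshape. The Haar operators' adjoints equal
their inverses (orthonormality), so analysis/synthesis are each other's
backward passes. Every backward implementation is compared against central
finite differences (rtol 1e-4 for layer primitives; 1e-3 through the full
model where finite-difference conditioning is worse). The tape frees
buffers as backpropagation consumes them, and an inference mode skips tape
construction entirely, bounding memory on full-resolution images.

Initialisation is He-normal for convolution weights, zeros for biases,
unit gamma / zero beta for batch norm, all drawn from one seeded generator
per model, so a (config, seed) pair is fully reproducible. Checkpoints
embed the configuration and are self-describing.

## Synthetic scenes

The generator emulates the statistics that matter to this architecture:
dark branching curvilinear structures of decreasing calibre on a bright
disc with radial illumination falloff, mild blur, additive Gaussian noise
and a circular field of view. Vessel trees are branching random walks
started on the disc rim heading inward (step 2 px, heading noise 0.15 rad,
branch probability 0.03 per step, width 3 px decaying by 0.8 at each
branch, 3 trees per 128×128 scene); anti-aliased stamping thresholded at
0.5 keeps ground truth binary without stair-stepping. These defaults were
set to give vessel coverage near 10% of the field of view, the density
scale of real fundus annotations; a 100-seed regression test pins coverage
inside (0, 0.35). Vessels are darker than background (fundus convention;
the contrast sign is configurable).

What the synthetic scenes do **not** contain: optic disc and fovea,
pathology, colour information, inter-image contrast variation, annotation
noise. Passing the synthetic-data tests therefore demonstrates that the
implementation is correct and trainable (gradients reach every parameter,
a small model fits a small set to Dice ≥ 0.9, the full pipeline runs end
to end) — not that the architecture attains any particular accuracy on
clinical data, which requires the real datasets and full-scale training.

## Scale of the shipped experiments

Tests and the acceptance script run reduced problem sizes chosen as the
smallest that exercise every code path meaningfully: widths (8, 16, 32,
64), 64×64 inputs, eight-patch overfit runs of ≤250 steps, scenes of
128×128. The full defaults (widths (64, 128, 256, 512), 4000 patches, 50
epochs) are the configured protocol and run unchanged, just longer.

## Known limitations

* CPU-only float64 training is orders of magnitude slower than a GPU
  framework; the package targets correctness and reference semantics, not
  throughput.
* Exact channel widths of the published variant of this architecture are
  not public; parameter counts will differ from any printed profile.
* Binary segmentation only; no ROC/AUC or topology-aware vessel metrics.
* SegNet encoders are randomly initialised (no VGG pretraining).
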