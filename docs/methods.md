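# Methods

This note documents the model, the numerical choices, and the deliberate
design decisions behind `mitseg`, in the spirit of a package methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Segmentation model

**Encoder.** A four-stage hierarchical Mix-Transformer. Stage geometry is
fixed by two constraints: the published stage resolutions (1/4, 1/8, 1/16,
1/32 of the input) and the published trainable-parameter totals of the
variant family. Together these pin down:

- *Overlapped patch merging*: stage 1 uses kernel 7, stride 4, padding 3;
  stages 2–4 use kernel 3, stride 2, padding 1. A stride-3 stage-1 merge is
  arithmetically incompatible with a 1/4-resolution first feature map, so
  stride 4 is used. The merge is a strided convolution followed by layer
  normalization of the token embeddings; "4×4 patches" describes the
  effective stage-1 token stride, not a non-overlapping cut.
- *Spatial-reduction attention (SRA)*: per-dimension reduction ratios
  R = [8, 4, 2, 1], i.e. key/value sequence-length reductions R² =
  [64, 16, 4, 1]. Reading the published reduction vector as per-dimension
  ratios of 64 would add multi-million-parameter reduction projections at
  stage 1 and contradict the parameter totals. The reduction is implemented
  literally as its defining equation: reshape each R×R window into one
  R²·C-feature token, project to C with a single linear map, layer-normalize.
  This is parameter- and function-identical to a stride-R convolution.
- *Attention*: per-head scaled dot-product softmax attention with bias terms
  on the query, key/value and output projections; head dimension C_i/N_i.
  The softmax is computed in max-subtracted form; the brute-force oracle
  tests use a 1e-5 absolute tolerance in float32.
- *Mix-FFN*: linear C→4C, 3×3 **depthwise** convolution on the token grid,
  GELU (exact erf form), linear 4C→C, residual connection. Expansion factor
  4 and depthwise (not dense) convolution are required jointly to land on
  the published parameter totals. The zero padding of the depthwise
  convolution carries positional information; no positional encoding exists
  anywhere in the model, so any input size whose stage-1 grid the reduction
  ratios tile is admissible without interpolation.
- Each stage ends with a layer normalization; two pre-norms per block
  (before attention and before the FFN).

**Variant registry.** The published specification table prints identical
depth/head/width rows for all four variants while listing four different
parameter totals; the registry therefore stores the canonical family
geometry — B0: depths [2,2,2,2], widths [32,64,160,256]; B2: [3,4,6,3] and
B3: [3,4,18,3] and B5: [3,6,40,3] at widths [64,128,320,512] — which
reproduces the published totals for B2/B3/B5 exactly (24,196,288 /
44,072,128 / 81,443,008). The published B0 total (3,319,292) differs from
the canonical architecture's count (3,319,392) by exactly 100 parameters;
no structural variation of this network family can produce a 100-parameter
difference, so the published figure is treated as a misprint and the
package reports the computed count. Parameter totals are interpreted as
encoder-only; `count_parameters` exposes `scope` so this is testable.

**Decoder.** All-MLP: per-level linear map to a unified width C (default
256; unspecified in the source, conventional for this decoder family and
excluded from encoder-scope parameter checks), bilinear upsampling to the
stage-1 grid, concatenation, linear fusion 4C→C, dropout, linear classifier
C→12. The fusion is a plain linear layer — the defining equations specify
`Linear` only, so no batch norm or ReLU is inserted. Bilinear interpolation
uses half-pixel centres with corner alignment disabled, implemented as
multiplication by fixed interpolation matrices (hence exactly
differentiable and bit-reproducible).

## Training and calibration

- Pixelwise unweighted cross-entropy on logits bilinearly upsampled from
  H/4×W/4 to the mask resolution (the alternative — downsampling the mask —
  would blend labels). Padded tile pixels are excluded via a validity mask.
- Adam, lr 6e-4, β = (0.9, 0.999), ε = 1e-8; batch size 8; 50 epochs;
  dropout 0.1 applied after the attention projection and twice inside the
  Mix-FFN and before the decoder classifier; layer-norm ε 1e-6. No learning
  rate schedule and no weight decay (a single rate is published; decay is
  unstated, so zero). Class imbalance is deliberately not reweighted.
- Initialization: truncated normal (σ = 0.02, clipped at 2σ) for linear
  weights, Kaiming-scaled normal for convolution weights, zeros for biases,
  ones for layer-norm gains.
- Reproducibility: all randomness (init, shuffling, dropout) flows from
  explicit `numpy` generators seeded by the run seed. With single-threaded
  BLAS, runs are bitwise reproducible; multi-threaded BLAS may reorder
  reductions, making runs reproducible in distribution only.
- *Temperature scaling*: one scalar T minimizes the validation negative
  log-likelihood of softmax(logits/T), solved by bounded scalar
  minimization on log T over [log 0.05, log 20] (the problem is 1-D and
  convex; no gradient machinery needed). T is fitted on validation pixels
  only. A degenerate single-class validation set yields T = 1 with a
  warning. Scaling by T > 0 is strictly monotone per pixel, so the argmax
  mask — and therefore accuracy and mIoU — are invariant under calibration.
- *Uncertainty*: u = 1 − max_c p_c of the calibrated posterior, bounded by
  [0, 1 − 1/12]; maximal exactly where the posterior is uniform.

## Data pipeline

- **Palette codec.** Masks are paletted PNGs; the codec is a strict
  bijection between palette colors and class indices 0..11 (class order
  BCC, SCC, IEC, GLD, FOL, INF, RET, HYP, PAP, EPI, KER, BKG). The exact
  published palette RGB values are not recoverable from text, so the default
  palette is twelve maximally distinct colors and is configurable.
  Off-palette pixels raise an error listing the offending colors and counts.
- **Resolution variants.** Images are downsampled by 2/5/10 with area (box)
  interpolation; masks with nearest neighbour (labels are never blended);
  the physical pitch becomes 0.67·factor µm/pixel.
- **Tiling.** Non-overlapping 256×256 grid (configurable), right/bottom edge
  tiles padded with white pixels and the background label — the H&E
  convention for empty slide — with padding recorded in a validity mask and
  excluded from loss and metrics. Tiles are bilinearly rescaled to 512×512
  (masks nearest-neighbour); 0-based, row-major, half-open tile coordinates
  support exact stitching, which restores the original mask on all unpadded
  pixels.
- **Splitting.** 80/10/10, stratified by (cancer type × biopsy type) with
  largest-remainder rounding per stratum and a global correction to the
  whole-set largest-remainder totals (290 specimens always split
  232/29/29). Augmentation (the 8 square symmetries, applied identically to
  image and mask) is intended for training tiles only, after splitting, to
  avoid leakage; this ordering is this package's choice, as the source does
  not state one.

## Synthetic fixtures

The generator emulates the statistical structure of the real corpus, not its
appearance: a background-dominant canvas (target 58.6% background, matching
the corpus class table, realized within a few percentage points), one smooth
tissue blob, depth-ordered anatomical bands (keratin/epidermis at the rim,
papillary then reticular dermis, hypodermis deepest), carcinoma lesions near
the epidermal side, and small gland/follicle/inflammation islands in the
dermis. Per-specimen metadata follows the corpus mixes (BCC:SCC:IEC =
140:60:90, shave:punch:excision = 100:58:132, largest-remainder apportioned).
Images are per-class base colors plus blurred Gaussian noise.

What fixtures do **not** model: stain physics, nuclei-level morphology,
staining variability, scanner artifacts, or ambiguous class boundaries.
Consequently, passing tests demonstrate that the pipeline is correct and
that the model can extract a learnable signal — they say nothing about
segmentation accuracy on real H&E slides, which additionally requires
pre-trained encoder weights and GPU-scale training.

## Problem sizes used in the test suite

The suite exercises the full-size encoders only where the claim demands it
(parameter counts for all four variants; pyramid-shape checks for B0 at
512×512 and 64×64). Everything involving optimization uses a miniature B0
(widths [8,16,24,32], one block per stage, decoder width 32) on 64×64
synthetic tiles: the learnability check trains 200 Adam steps on 8 tiles and
must beat the majority-class mIoU baseline. These sizes are the package's
choice of a minimal configuration that still exercises every code path —
attention reduction at all four ratios, multi-head splitting, tiling,
calibration — while keeping the default test run fast.

## Known limitations

- CPU-only NumPy execution: full-scale (512×512, B0+) training is
  impractical here; the package targets correctness, small-scale
  experiments, and serving as a readable reference.
- Checkpoint import from externally pre-trained Mix-Transformers requires a
  one-time key mapping into the flat checkpoint namespace
  (`encoder.stage{i}.block{j}.*`); no downloader is included.
- The published B0 parameter total is irreproducible (see above); all other
  variant totals are reproduced exactly.
- Metrics follow the macro conventions stated above; alternative F1
  averaging conventions are all reported (micro/macro/weighted) because the
  source's choice is not recoverable.
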