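# Methods

## The problem and the model

Breast-ultrasound (BUS) computer-aided diagnosis involves two coupled tasks:
segmenting the lesion region at pixel level and classifying the image
(normal vs lesion, or benign vs malignant). This package implements a
cross-task guided multi-task network that trains both heads jointly and lets
each task's intermediate prediction steer the other through attention soft
masks.

The forward pass, for an image `I ∈ [0,1]^{M×N}`:

1. **Feature extraction.** A convolutional encoder followed by atrous
   spatial pyramid pooling (ASPP) produces shared features
   `F' ∈ R^{D×H×W}` at a configurable stride (default 8). ASPP runs a 1×1
   branch plus one dilated 3×3 branch per rate, concatenates, and projects
   back to `D` channels; the multi-rate pyramid makes the features more
   robust to lesion scale.
2. **Coarse segmentation.** A decoder of four ×2 bilinear-upsampling stages,
   each followed by two convolution layers, ends in a 3-channel convolution
   and per-pixel softmax: the soft tissue mask `M = (M_l, M_m, M_b)`
   (lesion, mammary gland, background). With a stride-8 backbone, four
   doublings overshoot ×16, so the logits are resized bilinearly to the
   exact image size before the softmax; this preserves the four-stage design
   for any stride.
3. **Lesion classification.** The lesion attention module (LAM) forms
   `F_ma = F' ⊙ M_m`, `F_la = F' ⊙ M_l` (soft masks resized to the feature
   grid and broadcast over channels) and `F_LAM = F' + F_ma + F_la`. Global
   average pooling, an affine map to the per-class feature matrix
   `G_global ∈ R^{D1×C}`, and a second affine map to logits give the scores
   `H_score = softmax(logits)`. The masks are not detached — classification
   gradients flow back into the coarse-segmentation unit by design.
4. **Fine segmentation.** Two guided feature maps are fused:
   the category selection module (CSM)
   `F_CSM = [Conv(G_global) ⊙ H_scoreᵀ] · Conv(F')` (the shared features are
   projected to `C` channels so the matrix product is well formed), and the
   anatomical knowledge guidance module (AKGM), a non-local self-attention
   block whose query and key are multiplied by the gland mask:
   `S = softmax_keys((Q ⊙ M_m)ᵀ (K ⊙ M_m))`,
   `F_AKGM = α (S ⊗ V) + F'` with the scalar `α` initialized to zero, so
   AKGM starts as the identity and attention is phased in as `α` is learned.
   `F_fine = Concat[F_CSM; F_AKGM]` is decoded (same pattern as the coarse
   decoder) into a 2-channel softmax; channel 0 is the lesion probability.

## Objective and task weighting

`L_total = λ₁ L_cls + λ₂ (L_cseg + L_fseg)`, with cross-entropy for
classification and soft Dice for both segmentation heads (smoothing
`ε = 1.0` in numerator and denominator, which defines empty-vs-empty as
Dice 1; coarse Dice averages over all three channels including background,
which stabilizes early training). The two segmentation losses share one
weight, so the number of tasks is `K = 2`.

Dynamic weight averaging sets the weights once per epoch from the relative
descent rate of the epoch-mean task losses,
`w_k = L_k(t−1)/L_k(t−2)`, `λ_k = K exp(w_k/T) / Σ_i exp(w_i/T)` with
temperature `T = 2`; both weights are 1 for the first two epochs, and they
always sum to `K`. Epoch-mean losses are used rather than per-batch values
because batch ratios are far too noisy to steer the weighting.

## Training

Adam with β₁ = 0.9, β₂ = 0.99, ε = 1e-8. The full profile uses the reference
hyperparameters (learning rate 1e-4, batch 16, up to 100 epochs); early
stopping monitors the total validation loss (min mode, absolute comparison)
with patience 10 and restores the best-validation parameters. All randomness
(initialization, shuffling, phantom generation) derives from explicit seeds;
runs are bitwise reproducible on CPU.

The network is implemented in NumPy with reverse-mode automatic
differentiation (HIPS autograd); convolutions are custom primitives with
analytic adjoints so both passes stay in dense BLAS operations, and training
uses float32.

**Decoder normalization.** Each decoder convolution is followed by group
normalization (≤ 8 groups) before its ReLU. This is a deliberate addition to
the bare conv stack: a pure Dice objective optimized with Adam can drive an
unnormalized decoder's softmax into exact floating-point saturation on the
majority class, after which the minority-class (lesion) Dice gradient
vanishes identically and the lesion channel can never recover. Normalizing
decoder activations keeps the logits O(1) on optimization timescales and
eliminates this failure mode. The backbone itself stays normalization-free,
matching the VGG-style encoder convention.

## The phantom generator

Real BUS data (the datasets used to benchmark this architecture are private
or third-party) is replaced by a seeded synthetic phantom so every stage is
testable offline. Each phantom emulates the layered anatomy of a breast
sonogram: a bright skin/fat band (fraction 0.15 of height, intensity ~0.72),
a mid-intensity mammary-gland band (fraction 0.35, ~0.50), and a darker
muscle region (~0.28) with periodic bright rib-like blobs. At most one
hypoechoic lesion per image is placed fully inside the gland band — the
anatomical prior the network exploits — with intensity offset −0.25 against
the gland background. Benign lesions are smooth ellipses (axis ratio drawn
in [0.6, 1.0], both semi-axes kept within the configured radius range,
default 5–9 px at 64×64); malignant lesions are star polygons with 7–12
spikes and radial jitter, giving the classifier a shape cue analogous to
clinical morphology. The clean image is blurred (Gaussian, σ = 1.2) and
multiplied by unit-mean gamma speckle (sd 0.15 by default), which preserves
expected layer contrast; the pre-speckle image is kept in the sample
metadata so contrast properties can be asserted exactly. Labels are binary
(normal vs lesion) by default, with a 3-class mode (normal/benign/malignant)
behind a config flag.

What the phantoms do **not** model: beamforming and attenuation artifacts,
acoustic shadowing and posterior enhancement, probe-pressure deformation,
multiple or non-massive lesions, operator annotations burned into frames.
Passing tests therefore demonstrate that the architecture, losses, and
training loop function as specified and can learn this family of images;
they say nothing quantitative about performance on clinical data.

## Desk profile and problem sizes

All shipped experiments run a shrunk "desk" profile chosen as this package's
standard CPU-scale configuration: 64×64 phantoms, lightweight 4-stage
encoder (widths 8/16/24/32), D = 32, D1 = 16, decoder widths 16/8/8/4,
batch 8, 20 epochs over 200 training phantoms with 50 validation and 50
held-out test images. The desk learning rate is 3e-3: the desk network is
orders of magnitude smaller than the full profile and trains for only ~500
steps, so the full profile's 1e-4 is far below the stable fast rate at this
scale (3e-3 was selected from single-batch convergence behaviour; 1e-2 is
already unstable because the 1×1 output heads sit outside normalization).

## Numerical choices and conventions

- Coarse-mask channel order is fixed package-wide: 0 lesion, 1 gland,
  2 background; `hard_mask` breaks argmax ties toward the lower index.
- Mask-to-feature resizing and all decoder upsampling are bilinear
  (half-pixel convention), implemented as constant interpolation matrices so
  they are exactly linear and differentiable.
- Attention orientation: `S` is the row-softmax over the key axis of
  `(Q')ᵀ K'`, making each output position a convex combination of value
  vectors; query/key depth is `D' = max(1, D/8)`; `α` is a single scalar.
- The `N×N` attention matrix is materialized at feature resolution only
  (N = 64 at the desk profile, N = 1024 for 256×256 inputs at stride 8);
  larger inputs require a larger stride.
- Segmentation metrics are averaged per image ("per case"), classification
  metrics are pooled over images; AUC is the rank-based Mann-Whitney
  statistic with midrank tie handling. Empty-mask conventions: both masks
  empty → DSC = JI = TPR = 1, FPR = tFPR = 0; empty ground truth with false
  positives → DSC = JI = TPR = 0, FPR = 1, and tFPR is undefined (NaN),
  excluded from aggregation with a reported count. For a degenerate label
  set AUC is reported as NaN with a warning while threshold metrics are
  still computed.
- Classifier scores are thresholded at 0.5 by default (config-exposed).
- VGG16 is selectable as the encoder (cut at stride 8); pretrained weights
  are off by default and must be supplied as an `.npz` path — they are an
  optimization speed-up, not part of the method's math.
- No data augmentation anywhere: the training procedure is kept exactly as
  specified, and augmentation would confound parity checks.

## Known limitations

- CPU-only; the `N×N` attention and the pure-NumPy autodiff put realistic
  limits around 256×256 inputs.
- The phantom's simplicity means desk-scale scores (DSC, AUC) are not
  comparable to clinical benchmarks in either direction.
- The fine decoder reconstructs masks from stride-8 features without skip
  connections, bounding achievable boundary precision.
- Single-lesion evaluation only; multi-lesion images are out of scope.
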