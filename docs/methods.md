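# Methods

## Problem and scope

`nodulecam` implements a small, fully testable version of a lung-nodule
classification study: three convolutional networks — a 2D AlexNet variant,
a 3D AlexNet variant, and a lightweight "proposed" 3D CNN — classify small
cubic CT candidate crops as nodule vs. non-nodule, and gradient-weighted
class activation mapping (Grad-CAM) renders the voxels each decision rests
on. Patient CT data is replaced by synthetic phantoms with voxel-exact
ground truth, so every stage (architecture audit, training, evaluation,
explanation) runs on a desktop CPU in minutes and can be asserted against
oracles.

## Architecture reconstruction and audit

The three networks are published only as layer tables listing output
shapes and per-layer trainable parameter counts; kernel sizes appear
nowhere. For a cubic stride-1 convolution the count

    params = k^nd · c_in · c_out + c_out

is strictly increasing in `k`, so each printed count pins the kernel edge
length down uniquely (`derive_kernel_size` searches k = 1..11 and refuses
to guess). Parameter counts are therefore treated as the authoritative
architecture facts; printed output shapes, which are mutually inconsistent
in the proposed model's table, are derived rather than copied.

Two printed cells admit no integer kernel at their channel widths:
`18454` in the 2D table (the only consistent value is 3²·64·32+32 =
18464) and `53328` in the 3D table (3³·64·32+32 = 55328). These are
carried as explicit known-typo flags with corrected values; the audit
passes a layer flagged this way only when the built model realizes the
*corrected* count, and any other disagreement is a hard mismatch. The
proposed model's table additionally contains two stray rows (a pooling row
with an impossible 312-channel shape duplicated from the 3D AlexNet table,
and a 200-unit dense row pasted from the same source); both are dropped
from the canonical description.

The frozen proposed-3D layer order is

    conv(1→16, k6, same) → BN → conv(16→16, k2, same) → BN →
    conv(16→16, k4, valid) → BN → pool2 →
    conv(16→32, k2, valid) → BN → conv(32→32, k2, valid) → BN → pool2 →
    conv(32→64, k2, valid) → BN → pool4 → flatten(64) →
    dense(64→256) → BN → dropout → dense(256→2)

on a 27³ single-channel input. This reproduces every non-stray printed
count; the final pool kernel (4) is the unique choice that collapses the
4³ grid to 1³ and hence yields the flatten width 64 forced by the printed
dense count 16640 = 64·256+256. Padding is `same` exactly where a
preserved extent is needed and `valid` elsewhere. Batch normalization is
counted at four parameters per channel (scale, shift, running mean,
running variance), matching the printed 4·C cells; the running statistics
are stored but not trained.

Even kernels under `same` padding use the asymmetric convention (⌊(k−1)/2⌋
leading, ⌈(k−1)/2⌉ trailing zeros), which preserves the input extent for
every k.

## Numerical engine

No deep-learning framework is used: the layer set is small and fixed, and
Grad-CAM needs gradients at interior feature maps, so the package carries
a compact NumPy engine (`nodulecam.nn`) with hand-written backward passes,
verified end-to-end against finite differences (tolerance 1e-6 in float64)
and a loop-based convolution oracle.

Convolutions are evaluated as one GEMM per kernel offset (shift-and-
multiply): for each of the k^nd offsets a contiguous shifted view of the
padded input is multiplied by the corresponding kernel slice. For layers
with very few input channels these GEMMs degenerate into thin outer
products, so below 8 input channels the forward pass falls back to an
unrolled im2col matrix; the backward pass uses the offset decomposition
throughout. On one CPU core this puts a training epoch of ~250 volumes of
27³ voxels at roughly half a minute in float32.

Max pooling uses window = stride with floor semantics (trailing voxels
that do not fill a window are dropped), matching the printed halving
sequences. Dropout is inverted (identity at inference). All randomness
flows through explicitly seeded `numpy.random.Generator` objects:
identical (description, seed) builds are bit-identical, and training runs
are bit-reproducible.

Weight initialization defaults to uniform on [−1, 1] — the study fixes
only the maximum weight magnitude at 1, and this is its simplest reading —
with biases at zero and batch normalization at identity. A variance-scaled
alternative (`init="he"`) is available and is what the training-quality
tests use (see below). The initialization never affects the audit surface,
which counts parameters, not values.

## Grad-CAM

For a target convolutional layer with feature maps A^k, the heatmap for
class c is ReLU(Σ_k α_k^c A^k), where α_k^c is the spatial sum of
∂y^c/∂A^k and y^c is the *pre-softmax* class score. Design choices, each
of which the tests pin down:

- **Sum vs. mean weights.** The gradient sum and the gradient mean differ
  by the constant number of spatial positions z; since reported heatmaps
  are always min-max normalized, the two conventions are
  indistinguishable. The unnormalized sum is implemented.
- **Target layer.** Defaults to the last convolutional layer (the finest
  semantic grid), overridable by name.
- **Upsampling.** Trilinear (bilinear in 2D) interpolation to the input
  extent along the true receptive-field geometry: each target-layer cell
  is placed at its receptive-field center (`start + jump · i`, by the
  standard arithmetic over the preceding convolutions and pools) rather
  than proportionally stretched. With valid-padded convolutions in the
  chain the two differ by several voxels — e.g. the last conv layer's 4³
  cells sit at input coordinates 8/12/16/20, where a plain zoom would put
  the first cell near voxel 3 — which matters when heatmaps are compared
  voxel-wise against small masks. After resampling the map is min-max
  normalized, so it attains exactly 1 whenever any raw value is positive;
  a constant map normalizes to zero.
- **Correctness oracle.** On a network ending in global average pooling
  followed by a single linear classifier, ∂y^c/∂A^k is constant across
  positions and equals w_kc/z, so the Grad-CAM weights reduce exactly to
  the classifier weights and the heatmap to classical CAM. The test suite
  asserts this equivalence to 1e-5 on toy GAP networks in 2D and 3D,
  along with non-negativity, zero-gradient ⇒ zero-map, scale covariance,
  and bit-identical recomputation.

Gradients reach the target layer through the same backward passes used in
training, run in inference mode (running batch-norm statistics, dropout
off), which makes heatmaps deterministic.

## Phantom generator

Each phantom is a 27³ (configurable) float volume: flat background, one to
four bright cylinders of random orientation emulating vessels (distractor
anatomy), for positive samples one quasi-ellipsoidal nodule (radius 3–6
voxels, per-axis ±20% eccentricity, smooth radial intensity profile
1 − d²/2) at a uniformly random interior position, and optional additive
Gaussian noise. Vessels are composed by maximum rather than addition, so
overlapping vessels never exceed the vessel intensity: with the default
contrast (nodule 1.0, vessels 0.5 over background) and the noise turned
off, the brightest voxel alone separates the classes perfectly. This is
deliberate — the package ships a max-intensity threshold classifier whose
accuracy is 1.0 on the noiseless configuration and degrades monotonically
with the noise level, establishing *before any training* that the learning
task is well-posed and that a network failing to reach high accuracy is a
training defect, not a data defect.

The mask stored with each positive sample marks exactly the nodule's
voxels (strictly brighter than background in the noise-free volume); it is
the ground truth against which Grad-CAM localization is scored. Negative
samples carry empty masks.

What the phantoms do *not* emulate: lung anatomy, nodule texture classes,
HU calibration, scanner noise spectra, or the candidate-extraction stage
of real CT pipelines. Tests passing on phantoms therefore demonstrate that
the machinery is correct and that the classifier learns spatially
localized evidence; they say nothing about clinical performance.

## Study design and training

A balanced dataset (the study's scale is 1,000 + 1,000 volumes) is split
70/30 into a training pool and test set, stratified by label; 10% of the
training pool is held out for validation. At 2,000 volumes this yields
exactly 1,400 pool / 140 validation / 600 test. The validation set is
consulted every epoch; the test set is meant to be read once, and
`evaluate_test` emits a warning when invoked a second time against the
same manifest.

Training follows the published protocol: softmax on the two class scores,
mean cross-entropy (log-sum-exp form), Adam with learning rate 1e-4,
β1 = 0.9, β2 = 0.999, ε = 1e-8. Epoch count, batch size and stopping rule
are not published; defaults are 50 epochs, batch 32, early stopping with
patience 10 on validation loss, all configurable. Inputs are normalized
by the training-set standard deviation only (scale-only, the default):
the phantom background sits at zero, and keeping it there means the
zero-padding that `same` convolutions introduce at the volume borders is
indistinguishable from background. Classical z-scoring is available
(`standardize="zscore"`) but shifts the background below the padding
level, which imprints bright-rim artifacts on saliency maps. The model
state with the lowest validation loss (earliest on ties) is the one the
results object carries.

The package exposes training in statsmodels style: `NoduleClassifier`
binds data + architecture, `fit()` returns a `ClassifierResults` with the
history, `summary()`, `predict`, `evaluate`, and `grad_cam` methods;
functional wrappers (`train`, `predict`, `cross_entropy_loss`) cover
scripting.

### Problem sizes used in the tests

The published headline numbers (97.17% accuracy, AUC 0.97 on LUNA16) are
tied to the external CT dataset and are out of scope. The end-to-end
quality gate instead trains the proposed 3D CNN on the noiseless phantom
configuration — 400 volumes (280 training pool, 28 validation, 120 test),
10 epochs, batch 8, three seeds — and requires median held-out accuracy
≥ 0.95, AUC ≥ 0.98, and the Grad-CAM argmax inside the true nodule mask
for ≥ 80% of true positives. These sizes are the package's chosen
desk-scale study conditions: large enough for stable estimates, small
enough to run in minutes on one CPU core.

Two optimization settings of that phantom study deviate from the LUNA16
protocol's defaults, for reasons worth recording. First, the quality gate
trains with the variance-scaled initialization: with weights uniform on
[−1, 1] the initial class scores are large and badly conditioned, and a
full 30-epoch run on the phantoms plateaus far below the target (held-out
accuracy ≈ 0.83), while the scaled initialization converges within a few
epochs. The [−1, 1] reading remains the build default since the study
states it, and the choice is exposed per run. Second, the phantom study
uses Adam at 1e-3 rather than the 1e-4 used on LUNA16: a learning rate is
a per-dataset tuning choice, and at 1e-4 the roughly 400 optimizer steps
that a desk-scale epoch budget affords move the weights too little to
leave the initialization basin (measured held-out AUC plateaus near 0.95
after 30 epochs, against ≈ 0.98–1.0 within ten epochs at 1e-3). The
`TrainConfig` default stays at the protocol's 1e-4.

Grad-CAM localization in the gate is scored at the fourth convolutional
layer (11³ grid) as a single-voxel test: the argmax of the upsampled
heatmap must lie inside the true nodule mask. The default explanation
layer — the last conv layer — sits on a 4³ grid whose cells span ~7
voxels per axis, too coarse to place one voxel inside a radius-3–6
nodule; mid-network layers offer the best resolution/semantics
compromise. Even there, this is a demanding statistic for the classical
gradient-sum formulation: the per-map weights are global, so every
occurrence of a class-relevant feature (vessels included) is re-lit in
the combined map, and a few-voxel smear of a small nodule's evidence can
push the single argmax just outside the mask. A control experiment with
hand-built brightness-integrating filters localizes essentially every
phantom through the same heatmap/upsampling code path, so failures of the
argmax statistic on trained networks reflect how the learned features
distribute class evidence, not the mapping machinery. See Known
limitations.

## Evaluation

Confusion counts use the convention that a probability exactly at the
threshold is called positive (the tie rule is not published; one had to be
fixed). Ratios with zero denominators are NaN with an explicit
`undefined` flag, never silently zero — a degenerate evaluation should be
loud. AUC is trapezoidal integration of the ROC over all distinct score
thresholds, which equals the Mann-Whitney probability
P(s_pos > s_neg) + ½P(tie); the suite verifies the identity against an
exhaustive pairwise oracle at 1e-10 and against scikit-learn, and checks
label-swap antisymmetry. The study's stray "area elevation curve" naming
is read as the AUC it reports elsewhere; only AUC is implemented.

## Known limitations

- Voxel-level Grad-CAM localization of few-voxel targets is brittle.
  Heatmaps reliably highlight the nodule region (and CAM equivalence,
  alignment and the hand-built-filter control all verify the machinery),
  but the *single* brightest voxel of a trained network's map lands
  inside the small ground-truth mask only for a seed- and layer-dependent
  fraction of cases, because the gradient-sum weighting re-lights every
  instance of shared features and smears small-object evidence by the
  receptive field. Overlay inspection, not the bare argmax, is the
  supported use of the maps.
- The engine targets this layer vocabulary only (stride-1 convs, window =
  stride pooling); it is not a general-purpose autodiff.
- Real-data input is limited to NIfTI/NRRD crops; DICOM series reading and
  LUNA16 candidate resampling are out of scope.
- Phantom realism is intentionally minimal (see above).
- 10-fold cross-validation on real data is replaced by seeded single
  splits on phantoms.
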