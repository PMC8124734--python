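# Methods

This note documents the model implemented by `mscdunet`, the
synthetic data it is validated on, the numerical conventions that
affect results, and the design choices made where more than one
reasonable construction exists.

## Segmentation model

The network is a 3-D encoder–decoder operating on 32³ (configurable,
divisible by 4) multi-modality patches. Per modality there is an
independent encoder of two stages, each `[conv 3³ – BatchNorm –
ReLU]×2` followed by a multi-branch pooling step; channel width starts
at `base_width` (default 32) and doubles per stage. The deepest
features of all encoders are concatenated into a shared bottleneck;
a shared decoder of two stages (`deconv 2³ stride 2 – BN – ReLU`,
then `[conv 3³ – BN – ReLU]×2`) restores resolution, with skip
connections that concatenate the pre-pooling features of **all**
encoders at the matching stage. This fusion-by-concatenation design
keeps the single-modality variant well-defined: removing encoders
only shrinks the concatenated channel budget.

### Multi-branch pooling (MP)

Each encoder down-sampling step runs several pooling branches in
parallel — default kernels 5, 3, 2 in the first stage and 3, 2 in the
second — all with stride 2 and symmetric padding ⌊(k−1)/2⌋, so every
branch outputs exactly half the spatial extent for even inputs (this
is asserted as an invariant). Branch outputs are concatenated along
channels; the convolutions of the next stage restore the channel
budget. Max pooling is the default; average pooling is available as a
configuration (`mode: average`) for the pooling-mode ablation.
Averaging ignores out-of-grid positions (no zero dilution at
borders); max pooling treats out-of-grid as −∞.

### Multi-branch dense prediction (MDP)

An MDP head receives `n_classes · Σᵢ kᵢ³` channels (defaults
k = 1, 3, 4 and 4 classes: 368). Within one branch the k³ channels of
a class encode predictions for the k³ spatial offsets around each
voxel; channel `r·k² + s·k + t` holds offset (r, s, t). The per-class
map is the average of the offset channels sampled at their shifted
positions, with out-of-range samples handled by a border policy. The
offset→channel bijection is fixed as `r·k² + s·k + t`; any bijection
gives the same function class, but the convention must be stable
because the preceding 1×1×1 convolution learns against it.

- `border: replicate` (default) clamps shifted coordinates to the
  grid. Zero-padding would systematically attenuate border scores of
  an averaging operator, so it is offered (`zero`) but not default.
- Branch maps are combined by `concat_conv` (concatenate the
  |ks|·n_classes maps, then a learned 1×1×1 convolution — the
  default) or `average` (parameter-free).
- k = 1 is exactly the identity on its class channels; this is the
  plain-prediction-head limit and is tested bit-exactly.

MDP is linear in its input; the implementation is checked against an
explicit triple-loop oracle (tolerance 1e−6) and by a linearity
property test.

### Side outputs, fusion and loss

Three heads tap the decoder at 1/4 scale (bottleneck), 1/2 scale
(after the first decoder stage) and 1/1 scale (after the second).
Each head is either a plain 1×1×1 convolution to class logits or a
1×1×1 convolution into an MDP head, selected per-branch by
`branch_mdp` (default `[true, true, false]`: MDP on the two coarse
branches, plain head at full resolution — the fusion variant that
performed best in our ablation grid). Head outputs are upsampled to
full patch resolution by trilinear interpolation (half-voxel aligned;
implemented as a linear operator per axis so its adjoint is exact in
the backward pass).

The fused prediction is the softmax of `Σ_h f_h · A_h`, where `A_h`
are the upsampled side logits and `f` is a learnable 3-vector
initialized to `[1, 1, 1]`. The training loss is the sum of the fused
class-weighted cross-entropy and the β-weighted side cross-entropies
(β default `[1, 1, 1]`). Class weights ω default `[1, 1, 2, 2]`
(tissue classes WM/CSF up-weighted against the large background).
Cross-entropies are normalized per voxel so loss magnitudes do not
depend on patch size; β and ω semantics are unaffected. The class
weight ω is applied in the fused term as well as the side terms (one
cross-entropy definition throughout).

### Autodiff core

No deep-learning framework is used. `mscdunet.nn` is a small
reverse-mode autodiff engine over numpy arrays with explicit backward
passes for conv3d (im2col + GEMM, channel-major columns), transposed
conv 2³/stride 2, max/average pooling, trilinear upsampling, batch
normalization (batch statistics in training, running statistics in
evaluation, momentum 0.1, ε 1e−5), ReLU, concatenation, weighted sums
and weighted softmax cross-entropy. Every backward pass is verified
against central finite differences (relative error ≲ 1e−8 in
float64). Weights use Xavier-uniform initialization from a seeded
generator; construction order is deterministic, so a seed fully
determines the initial model.

## Synthetic phantoms

The phantom generator provides ground-truth-labeled volumes with the
structural features that make brain tissue segmentation hard, without
claiming anatomical realism:

- **Geometry**: nested shells — WM core inside a GM shell inside a
  CSF shell inside background — obtained by thresholding a radial
  distance field perturbed by a smooth random field
  (`surface_irregularity`, default 2 voxels) that roughens the tissue
  boundaries.
- **Intensities**: drawn per class and modality from a configurable
  (mean, std) table. The default table gives adjacent tissue classes
  a separation of about 1.5 pooled standard deviations once the
  additive noise (default σ = 5) is included, so class distributions
  overlap at boundaries; the three default modalities have different
  contrast orderings (T1-like, inversion-recovery-like, FLAIR-like),
  making multi-modal input genuinely informative.
- **Artifacts**: a smooth multiplicative bias field
  `exp(amplitude · s(x))` with `s` a very-low-frequency unit-variance
  field (amplitude default 0.2), emulating MR intensity
  inhomogeneity, plus i.i.d. Gaussian noise.

Everything is determined by the spec seed; cohort generation derives
per-subject seeds (`seed + i`) and jitters shell radii (a common
0.92–1.0 scale plus ±2 % per shell) so subjects differ in anatomy.

What the phantom does **not** model: cortical folding and thin gyri,
partial-volume mixtures, registration error between modalities,
infant-brain myelination contrast, and pathology. Passing the
phantom-based tests therefore demonstrates that the implementation
learns and generalizes under controlled intensity overlap, bias and
noise — not that it reaches any particular accuracy on clinical data.

## Preprocessing, sampling, augmentation

Normalization is smooth-subtract → CLAHE → z-score: subtract a
Gaussian-smoothed copy (σ default 8 voxels; removes smooth background
and makes the result invariant to global intensity offsets), apply
contrast-limited adaptive histogram equalization (clip limit 0.01,
8×8×8 tiles; volumetric by default, per-axial-slice behind a flag),
then subtract the global mean and divide by the global standard
deviation. A constant volume raises an explicit degenerate-input
error rather than dividing by zero.

Training patches are same-center crops of all modalities plus the
label map, with the center drawn uniformly over all fully-inside
positions (verified by a χ² test on the empirical center
distribution). Augmentation applies one shared geometric transform to
all modalities (linear interpolation) and the labels (nearest
neighbor): per-axis flips, a rotation of up to ±10° about a random
axis pair, isotropic zoom 0.9–1.1, shifts up to ±4 voxels, and a
small elastic deformation (smoothed displacement field, amplitude
1.5 voxels, smoothing σ 3). All random draws happen unconditionally
so rng consumption — and hence reproducibility — does not depend on
which transforms fire.

## Training and inference

Training runs ADAM (β = 0.9/0.999, ε 1e−8) for a configured number of
iterations with a step-decayed learning rate (default 1e−3, ×0.1
every 5000 iterations) and batch size 4. The sub-volume budget
(default 72 000) caps total patches drawn, so
`effective iterations = min(iterations, budget // batch)`. A
non-finite loss aborts with the iteration index and learning rate.
Training is deterministic under the config seeds in single-threaded
execution.

Full volumes are segmented by sweeping 32³ windows at stride 8 along
each axis; the window lattice is clipped so the last window ends at
the volume edge, guaranteeing full coverage. Each voxel's label is
the most frequent hard label among covering windows (probability
accumulation available behind `mode="prob"`), ties broken toward the
smallest class index — a stable, documented rule. Volumes smaller
than the patch are edge-padded and cropped back. Vote conservation
(Σ_class counts = coverage) is an asserted invariant. Only the fused
output votes; side outputs are auxiliary training signals.

## Evaluation metrics

Per class: Dice (percent; both-empty defined as 100), 95th-percentile
symmetric Hausdorff distance (mm), absolute volume difference
(percent of truth volume), and average symmetric surface distance
(mm). Conventions that materially affect the numbers, fixed and
documented here:

- surface voxels are foreground voxels with at least one 6-neighbor
  outside the mask, out-of-grid counting as outside;
- distances are Euclidean between surface-voxel centers in physical
  coordinates (index × spacing);
- percentiles interpolate linearly between order statistics;
- metrics undefined on empty structures raise an explicit error, and
  classes absent from the ground truth are reported as missing values,
  never silent zeros.

HD95 and ASD scale exactly with voxel spacing; Dice and AVD are
spacing-free. All four are validated against O(n²) all-pairs oracles.

## Problem sizes used in tests and the acceptance script

The self-contained study uses 64³ phantoms, three training subjects
and one held-out subject, a 3-modality network with `base_width` 8
and 16³ patches, trained for 300 ADAM iterations (batch 4). For such
short runs the step decay is rescaled proportionally to ×0.5 every
100 iterations: at a constant 1e−3 the short runs are
optimization-unstable (held-out Dice varying by ~0.2 across seeds),
while the rescaled decay makes both the multi-scale network and the
plain-U-Net comparator converge reproducibly. The tiny runs skip
augmentation (it slows convergence at this budget and is exercised by
its own tests). Held-out evaluation in the test suite votes at stride
16; the acceptance script uses the default stride 8.

## Known limitations

- CPU-only numpy execution: the default-width network is usable for
  inference but far too slow for the full 18 000-iteration training
  schedule; the package's empirical claims are restricted to the tiny
  configuration above.
- The phantom's realism limits (listed above) mean reported Dice/HD95
  values are not comparable to clinical benchmark scores.
- Batch normalization uses per-batch statistics with small batches
  (4), which adds gradient noise; running statistics are only used in
  evaluation mode.
- `base_width` trades accuracy for time; the default 32 matches the
  architecture description, not any particular parameter count.
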