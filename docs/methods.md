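# Methods

## Problem

The masseter muscle (MM) is a bilateral masticatory muscle whose volume and
shape matter for orthodontic and orthognathic planning.  Cone-beam CT
(CBCT), the routine dental 3-D modality, has poor soft-tissue contrast: the
muscle compartment's Hounsfield-unit (HU) distribution has roughly the same
center as in conventional CT but a much larger variance, which makes manual
delineation unreliable.  This package re-implements an automatic approach:
one 3-D segmentation network trained jointly on CBCT and CT volumes against
ground truth defined on the CT, predicting three classes — background, left
MM, right MM.  Because the clinical scans behind the original results are
not public, the package ships a synthetic phantom generator so that every
stage is testable end to end.

## Coordinate and label conventions

All volumes are canonicalized to the RAS+ axis order on load.  Class 1
("left") is, by repository convention, the structure whose centroid lies on
the +x side of the canonical grid and class 2 ("right") the one on the −x
side.  Nothing downstream ever mirrors an image: a reflection would swap
the meaning of the two labels, so the augmentation explicitly excludes
flips and chirality is preserved from generator to metric.

## Phantom generator

Each case is a small head-like scene on a common grid (default 64³ voxels
at 0.5 mm): an ellipsoidal soft-tissue body in air, a midline bone plate,
and two mirrored ellipsoidal muscles lateral to the plate whose lateral
radii shrink linearly toward the superior tip (`taper`, default 0.5).  The
taper reproduces the thin superior extent that is the classic failure
region of automatic MM segmentation.  The same geometry is rendered as a
pseudo-CT and a pseudo-CBCT around identical per-compartment mean HUs with
per-modality noise SDs:

| compartment | mean HU | CT SD | CBCT SD |
|---|---|---|---|
| muscle | 60 | 15 | 60 |
| fat/soft tissue | −100 | 20 | 50 |
| bone | 900 | 60 | 120 |
| air | −1000 | 20 | 40 |

Only the ordering (CBCT muscle variance > CT muscle variance) is an
empirical fact about the modalities; the magnitudes are configuration and
the generator validates the ordering.  Intensities are
`mean + sd * G` where `G` is a smooth Gaussian random field rescaled to
unit pointwise SD (correlation length `smoothing_mm`, default 0.6 mm), so
per-compartment sample means and SDs converge to the configured values
while the noise is spatially correlated.  Compartment boundaries are sharp;
the generator deliberately does **not** model partial-volume blur, scatter,
beam hardening or ring artifacts, so passing the end-to-end tests shows the
pipeline is correct, not that it reaches clinical accuracy on real CBCT.

The midline bone plate is what makes the left/right distinction learnable
by a translation-equivariant network: each muscle is locally a mirror image
of the other, and the side can only be inferred from which side of the
voxel the bright bone lies on.

A simulated observer (`simulate_observer`) warps the ground-truth
boundaries through a smooth random displacement field (pointwise SD in mm),
providing paired "annotations" for exercising the agreement statistics.

Per-case sub-seeds are spawned deterministically from one master seed;
a dataset manifest records ids, sub-seeds, the spec hash and the
train/val/test split.

## Intensity pipeline

HU values are clipped to [−325, 400] — the 0.5/99.5 foreground quantile
window of the clinical dataset the method was developed on — then z-scored
with the pooled foreground mean/SD of the training cases (both modalities
pooled), the nnU-Net-style normalization that puts CBCT and CT on one
intensity scale.  The quantile rule itself
(`foreground_quantile_bounds`, linear-interpolation quantiles over pooled
foreground voxels) is exposed for recomputing the window on a new dataset;
the fixed window is the default.  Resampling to a common grid (trilinear
for intensities, nearest-neighbor for labels) is available; phantoms are
generated pre-aligned, so the default experiment does not resample.

## Network

A two-level U-shape ("U²"-style) with four stages.  Every stage is a
ReSidual U-block (RSU): an input transform to the stage's output width, a
nested encoder–decoder at a reduced `mid` width over `depth` internal
scales (2× max-pooling down, trilinear 2× up, skip concatenations), and a
residual addition of the input transform.  The deepest stage replaces
pooling with growing dilation (1, 2, 4, …) so it works at bottleneck sizes;
dilated taps that fall entirely outside the grid reduce exactly to the
center tap.  Between stages the outer encoder pools 2× and the decoder
upsamples 2× and concatenates the encoder skip.  Each decoder scale and the
bottleneck carry a 3-class score head (deep supervision, 4 side outputs);
a fused head combines all side outputs at full resolution and is the
prediction head.

Defaults: stage channels 16/32/64/128, RSU depths 5/4/3/2, mid widths =
half the stage channels, LeakyReLU slope 0.01, instance normalization
(batch size 2 makes batch statistics unreliable), He-style seeded
initialization.  Inputs must be divisible by 2^(stages−1) = 8 per axis.

The engine underneath is a small tape-based reverse-mode framework on
NumPy (`masseg.nn`): channels-last float32 tensors, 3×3×3 convolutions
evaluated as 27 shifted BLAS GEMMs on flat contiguous views of the
zero-padded input, with hand-derived backward passes for every op.
Gradients were verified against central finite differences in float64
(worst relative error ≈ 1e−6 across random parameters).  Everything is
deterministic given seeds; there is no threading.

## Training

Loss = soft Dice over the two foreground classes (ε = 1e−5) plus
cross-entropy, equally weighted, applied at every output scale against
nearest-neighbor down-sampled ground truth (deep supervision, all scale
weights 1).  Optimizer: SGD with momentum 0.9, weight decay 0.  The
learning rate ramps linearly 0 → 1e−3 over the warm-up iterations and then
follows a half-cosine to 0 (defaults 300 / 20 000 iterations, batch 2).
Patches are sampled with a 50 % foreground bias and augmented by a random
3-D rotation (±15° per axis) composed with a random isotropic rescale
(0.85–1.15); the linear part always has positive determinant — no
reflections, by construction.  Whole-volume training is infeasible at
0.3-mm resolutions, so training is patch-based (default 48³).

## Inference

Sliding-window prediction with 50 % overlap; per-voxel softmax
probabilities of the fused head are averaged uniformly over windows, the
label is the argmax with ties broken toward the lower class index, and the
output grid equals the input grid.  Volumes smaller than the patch are
edge-padded and cropped back.  A per-class largest-connected-component
filter (26-connectivity) is available but off by default, since the
published results report raw model output.

## Metrics and statistics

* DSC per class; the three-class "mean" is the unweighted mean over
  {background, left, right}.  The published two-class formula
  ½(DSC_Seg + DSC_Back) is exposed separately; on three-class maps the
  unweighted three-class mean is what reproduces the published "Mean"
  columns (e.g. (99.96 + 91.56 + 90.94)/3 = 94.15).
* Average Hausdorff distance in physical mm via exact Euclidean distance
  transforms; directed both ways, symmetrized as the mean of the two
  directions, side-mean as the mean of the left and right symmetric
  values.  Both-empty DSC = 1, one-empty DSC = 0; aHD on an empty
  structure is an error (reported as NaN in batch evaluation).
* Revision fraction: per class, 100 × |symmetric difference| / |revised|,
  falling back to the original count (with a warning flag) if the revised
  structure is empty.
* Aggregates: mean, SD (n−1) and t-based 95 % CI of the mean.
  Bland–Altman limits of agreement use the 1.96 multiplier; the paired
  t-test is two-sided with n−1 degrees of freedom.

## Scaled-down end-to-end experiment

`masseg.experiment.run_phantom_experiment` generates 12 phantom cases
(8 train / 4 test) on 64³ grids, trains a reduced network (channels
8/16/32/64, depths 5/4/3/2) for 500 iterations of batch 2 on 32³ patches
(warm-up 50), and scores the held-out cases in both modalities plus the
CBCT-vs-CT prediction agreement.  These problem sizes are the package's
desk-scale choice: one full run takes on the order of ten minutes on a
single CPU core.  With the default conditions the held-out foreground DSC
is ≈ 0.84–0.91 per structure, the symmetric aHD well under 1 mm, and the
cross-modal DSC ≈ 0.95.

## Numerical and design notes

* Quantiles use linear interpolation between order statistics; pooled
  quantiles are therefore only asymptotically invariant under duplicating
  a case.
* Conv biases feeding instance norm are mathematically inert (the
  normalization removes additive constants); they are kept for uniformity
  and their gradients are exactly zero.
* Ground-truth down-sampling picks every 2^s-th voxel (nearest-neighbor
  from index 0), preserving the label alphabet at every scale.
* Checkpoints are a single `.npz` (parameters + JSON-encoded config +
  init seed); re-initialization from the same seed and config is
  bit-identical.
* Known limitations: no DICOM ingestion, no registration (paired phantoms
  are generated pre-aligned), no test-time augmentation or ensembling, no
  physically realistic CBCT artifact model, and no claim that phantom
  accuracy transfers to clinical data.
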