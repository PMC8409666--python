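# Methods

## Problem and pipeline

Gadolinium-enhancing MS lesions are segmented in two stages: a slice-wise 2D
U-Net produces a voxelwise lesion probability per 2D slice of a co-registered
multi-channel volume, the slices are restacked and binarized, and a random
forest then classifies each 3D connected component as lesion or false
positive. The two-stage split reflects the failure mode of slice-wise
models: they localize enhancement well but, lacking 3D context, produce
spurious small components that a cheap 3D-feature classifier removes.

All volumes are assumed co-registered and intensity-normalized already;
registration, bias-field correction and skull stripping are out of scope.
The grid convention is `(channel, slice, row, column)` with the slice axis
the thick (nominally 3 mm) axis, 0-based indices, half-open bounding boxes.
Inputs whose spatial shape differs from the nominal 64×256×256 template grid
trigger a warning, not an error: the network is fully convolutional and the
package is routinely exercised on smaller grids.

## Network

Encoder: five depths of (two 3×3 convolutions, each followed by batch
normalization then ReLU) with 32, 64, 128, 256, 512 filters and 2×2 max
pooling between depths; the 512 stage is the bottleneck. Decoder: four
stages of parameter-free 2×2 nearest-neighbour upsampling, concatenation
with the matching encoder skip, then two 3×3 conv+BN+ReLU at the skip's
width (256, 128, 64, 32). Head: 1×1 convolution + sigmoid, clamped to
(1e-7, 1−1e-7) so downstream logarithms are finite. With 10 input channels
this is 7,854,561 trainable parameters; `count_parameters` computes the
closed form and the builder is asserted against it. A learned
(transposed-convolution) decoder would add ~1.7 M parameters and break that
accounting, which is why upsampling is non-learned. Batch normalization is
placed after the convolution and before the activation; weights are
He-uniform initialized from a configurable seed; 3×3 kernels and "same"
padding throughout. Input spatial sizes must be divisible by 16 (four
poolings).

The layers, backprop and Adam live in `gadseg._nn`, written directly in
NumPy. This keeps the package dependency-light and fully deterministic given
the seed and BLAS thread count; the backward pass is validated in the test
suite against finite-difference directional derivatives and against
loss-decrease behavior in real training runs. The cost is speed: the
implementation is sized for desk-scale experiments
(tiny widths, 64×64 slices), not clinical-scale training.

## Losses

Per-voxel cross-entropy uses probabilities clamped to [1e-7, 1−1e-7].
Bootstrapped cross-entropy selects, over the *whole batch's* N voxels, the
K with the largest per-voxel loss and averages them; ties at the selection
threshold (the (K+1)-th largest loss) are broken by ascending voxel index so
exactly K voxels are selected and the 1/K normalizer is well defined. When
K ≥ N the loss equals plain mean cross-entropy; it is non-increasing in K
and bounded below by the mean cross-entropy — both asserted as properties.
The printed definition of the selection in the source material inverts the
inequality (which would select the easiest voxels); the implementation
follows the stated intent and the standard hard-example-mining reading.
Clinical-scale K values are 256, 1536, 3072 at batch size 16; K is a batch
budget, not a per-slice one. Dice loss carries an optional smoothing term
(default 1.0 during training, so empty-batch gradients are finite; the bare
loss with smooth=0 raises on two empty masks rather than returning an
arbitrary value).

## Training

Batches are consecutive, non-overlapping runs of `batch_size` slices within
one scan; a trailing remainder is dropped, and batches never span scans.
Lesion-balanced sampling keeps every batch containing a lesion voxel and
keeps an all-empty batch with probability `keep_empty_prob` (default 0.1 —
the enrichment rate is not prescribed anywhere; 0.1 preserves heavy positive
enrichment while exposing background variety). The optimizer is Adam with
beta1 = 0.5 ("momentum 0.5") and learning rate 1e-4 at clinical scale.
Validation after each epoch is the mean per-image 3D Dice of binarized
(threshold 0.5) restacked predictions, and the best-validation checkpoint is
returned. Binarization at 0.5 is the canonical choice and is configurable.

Desk-scale defaults (`TrainConfig.desk_scale`): encoder widths 8–128
(~0.5 M parameters), Dice loss, learning rate 3e-3, batch size 4, 10 epochs.
Rationale: ten epochs over a 12-scan cohort of 32×64×64 phantoms is only a
few hundred optimizer steps, so the clinical-scale step size (1e-4) cannot
converge; a tiny network on small, high-contrast phantoms tolerates the
larger step, and Dice loss is the most robust of the three at this scale.
The end-to-end experiment (`pipeline.run_end_to_end`) splits 12 phantoms
6/2/4 into train/validation/test, fits the forest on candidates from the
train+validation scans, and evaluates before/after filtering on the test
scans; it completes in under a minute on one CPU.

## Phantoms

The generator emulates the *structure* of a preprocessed clinical scan, not
MR physics. Anatomy is nested ellipsoids — brain envelope, CSF rim,
cortical GM ribbon, WM interior, two lateral ventricles — and the five
probability channels are Gaussian-smoothed tissue indicators, renormalized
so GM+WM+CSF ≤ 1 per voxel; the lesion prior is a smoothed periventricular
shell (maximum 0.7). Lesions are placed in eroded WM, weighted by the
lesion prior, with exact voxel counts: an anisotropic quadratic form is
evaluated on a local window and the n smallest-valued voxels form the
lesion (ovoid), or voxels k+1…k+n with the innermost k ≈ 0.35 n as a
non-enhancing core (ring; only for sizes ≥ 15, below which discrete rings
disconnect). Placement enforces pairwise 6-connected disjointness via a
one-voxel dilated occupancy mask and retries up to 200 positions before
declaring the spec infeasible.

Intensities are tissue-weighted sums of per-contrast base values plus
lesion deltas: +`lesion_intensity` (default 0.5) on T1 post-contrast,
+0.05 on T1 pre (no enhancement), +0.4/+0.35/+0.2 on FLAIR/T2/PD; ring
cores get −0.25 on T1 post. Per-scan, per-channel gain jitter
(SD `contrast_jitter` = 0.1) and offset jitter emulate the protocol
variability of routine non-standardized MRI; Gaussian noise
(SD `noise_sd` = 0.05) is added to the MRI channels only — probability
channels stay noise-free, as template priors would be. Cohorts draw
lesion-bearing scans with a configurable prevalence (the routine-practice
reference value used in tests is 6.5%).

What the phantoms do *not* capture: realistic lesion texture, vascular and
choroid-plexus enhancement mimics (the dominant clinical false-positive
sources), partial-volume effects beyond smoothing, registration error, and
scanner-specific artifacts. Passing the end-to-end test therefore shows the
pipeline's machinery is correct and trainable, not that clinical accuracy
transfers.

## Candidates and forest

Components use strict 6-connectivity (face adjacency); the minimum lesion
size is 5 voxels, inclusive, applied to predicted *and* manual components.
The 75-feature layout is fixed: 9 location (centroid, bounding-box start and
extent in x/y/z voxel units; "slice location" is the z components), 1
scan-level candidate count (post size-filter, identical across a scan's
candidates), 5 shape (voxel count; mean and SD of the eigenvalues of the
second-central-moment matrix of voxel coordinates *in millimetres*; axial =
largest eigenvalue, radial = mean of the two smaller — DTI vocabulary
borrowed as shape descriptors), and 60 intensity (mean/SD/sum inside and in
the surrounding shell for each of the 10 channels). The "surrounding" is a
one-voxel face-adjacent dilation shell clipped to the grid (width
configurable); channels absent from a reduced contrast configuration are
zero-filled so the layout never changes within an experiment. Bounding-box
"extent" is the half-open box width; this is the adopted reading of a depth
measure that is otherwise undefined.

Forest training labels candidates with the same one-voxel-overlap rule used
at evaluation (no separate labeling rule exists; using the same rule avoids
ambiguity). Hyperparameters are not prescribed anywhere: 100 trees,
unlimited depth, balanced class weights, decision threshold 0.5, all
configurable, deterministic given the seed (scikit-learn
`RandomForestClassifier`). Filtering only removes components, so the
filtered mask is a subset of the input and sensitivity cannot increase.
In the end-to-end pipeline, if the training candidates are single-class
(e.g. a well-trained network yields no false positives ≥ 5 voxels), the
filter stage is skipped as an identity rather than failing; `fit_rf` itself
still raises on single-class input.

## Evaluation

Lesion matching is hybrid by construction: TP and FN are counted over
manual lesions (carrying manual sizes), FP over predicted components
(carrying predicted sizes). This is the only convention under which
published stratified sensitivities and FDRs are exactly recomputable from
their count tables, and it is what the acceptance tests assert. Undefined
ratios (0/0) are reported as NaN, never coerced to 0 or 1. Size strata
5–10 / 11–20 / 21–50 / 51–100 / >100 voxels partition the admissible sizes,
so totals equal sums over strata.

Mean 3D Dice averages per-image Dice over images with at least one manual
lesion; lesion-free images (0/0) are excluded, which keeps the mean finite
on cohorts that include healthy scans. The count confusion matrix is
predicted × true over {0, 1, ≥2}; normalization is by true-category column
totals (each column sums to 100%), and overall accuracy is the diagonal sum
over all scans. Per-size-group Dice has no canonical definition;
`dice_by_size_group` adopts a restricted-mask reading — Dice between the
union of a stratum's manual lesions and the union of predicted components
overlapping them — and labels it explicitly as a choice.

## Determinism and numerics

Every stochastic component (phantoms, cohort draws, weight init, batch
sampling, forest) takes an explicit seed; fixed-seed reruns of simulation
and evaluation are bit-identical and training reproduces its epoch-1 loss
exactly on the same machine and thread count. Probability clamps are 1e-7;
batch-norm epsilon 1e-5, running-stat momentum 0.9; max-pool gradient ties
route to the first maximum; top-K ties in the bootstrapped loss break by
voxel index. Checkpoints are NumPy `.npz` archives embedding the
architecture spec.

## Known limitations

- NumPy training is single-process and orders of magnitude slower than a
  GPU framework; clinical-scale replication (hundreds of 256×256 scans,
  full-width network) is out of reach by design.
- The phantom's simplicity means forest feature importances on phantoms
  need not match those seen on clinical data, beyond the coarse pattern
  that enhancement intensity and location/prior features discriminate.
- Batch normalization statistics come from small desk-scale batches;
  eval-mode predictions from an untrained or barely-trained network can
  saturate, which is why the head clamp exists.
- The CLI stores masks as NIfTI with the header's spacing but performs no
  orientation handling beyond preserving what the header declares.
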