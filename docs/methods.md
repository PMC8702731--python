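# Methods

## Problem and model

`neuroseg3d` segments three anatomical structures around the trigeminal
root entry zone in 3D MR angiography: the brainstem (class 1), the
cerebrovasculature (class 2) and the trigeminal nerve (class 3), against
background (class 0). The clinical motivation is neurovascular compression
(NVC): a vessel pressing on the nerve root, whose assessment needs accurate
surfaces for all three tissues at once.

The segmenter is a two-stage cascade trained end to end:

1. **Coarse stage.** An encoder–decoder for tubular structures whose
   feature extractors are multi-scale residual blocks. Each block applies a
   1×1×1 convolution, splits the channels into `s = 4` equal subsets
   `x_1..x_s`, and computes

       y_1 = x_1,
       y_2 = σ(B(K(x_2))),
       y_i = σ(B(K(x_i + y_{i-1}))),  2 < i ≤ s,

   with `K` a 3×3×3 convolution, `B` batch normalization and `σ` ReLU; the
   `y_i` are concatenated and fused by a 1×1×1 convolution inside a
   residual skip. Subsets reached later have passed through more stacked
   3×3×3 kernels, so one block mixes several receptive-field sizes — useful
   when the targets range from a brainstem to a nerve a few voxels thick.
   A channel/spatial self-attention module sits at the bottleneck
   (learnable scalars initialised to zero, so it starts as an identity);
   it can be disabled by config. The channel softmax of the coarse logits
   is the 4-class confidence map `P ∈ [0,1]^{4×Z×H×W}`.

2. **Refine stage.** The raw volume `I` is concatenated with `P` into a
   5-channel input `F = cat(I, P)`, processed by a plain 3D U-Net with a
   flat per-layer width (default 32); its 4-channel output features are
   summed with `P` (a residual connection that preserves the coarse
   structure) and projected by a 1×1×1 convolution back to 4 classes.
   Whether the summed map is the softmaxed `P` or raw logits is switchable
   (`sum_probabilities`, default: probabilities).

Both plain residual blocks and the multi-scale blocks are implemented so
the three ablation arms — `resblock`, `res2block`, `res2block+refine` —
differ only in the component under study.

### Compute backend

The networks run on a compact NumPy reverse-mode autodiff engine
(`neuroseg3d.nn`) written for this package: channels-last volumetric
tensors, shift-and-matmul 3D convolution, 2× max pooling / nearest
upsampling, batch normalization, softmax/log-softmax, batched matmul for
the attention, and Adam. Every op's analytic gradient is verified against
central finite differences in float64. The engine is single-threaded
NumPy/BLAS and fully deterministic given a seed.

## Loss

With the nerve occupying well under 1% of the working volume (roughly 3
axial slices), training uses

    L = α·L_wce + (1−α)·L_dice,  α = 0.5,

* `L_wce`: cross-entropy averaged over voxels with class weights
  (background, brainstem, vessel, nerve) = (1, 5, 20, 300). The reduction
  over voxels is a mean (not a sum) so that α keeps its meaning across
  crop sizes.
* `L_dice`: soft multi-class Dice,
  `1 − (1/C)·Σ_c (2Σ p_c g_c + ε)/(Σ p_c² + Σ g_c² + ε)` with Laplace
  smoothing `ε = 1`. A variant that squares the numerator terms exists
  behind `squared_numerator` for comparison only; it is not zero-minimized
  at perfect soft predictions and is never used for training.
* The loss applies to the refined output; an auxiliary coarse-stage term is
  available behind `aux_coarse_weight` (default off).

## Preprocessing

Volumes are resampled to isotropic 1 mm spacing (linear for images,
nearest for labels; output shape `round(shape·spacing/target)` per axis),
center-cropped to the (32, 96, 96) working grid (zero-padded symmetrically
if smaller, with the padding event logged), and min-max normalized to
(0, 1) per volume (a constant volume maps to zeros). During training a
random flip (axis uniform over the three) and a random small affine
(in-plane rotation ≤ 10°, isotropic scale in [0.9, 1.1], translation ≤ 5
voxels) are each applied with probability 0.5, identically to image
(linear) and label (nearest); normalization happens after augmentation.
At test time only normalization is applied. Interpolation orders are a
package choice; nothing finer is claimed.

All arrays are (Z, H, W) — slices first — with voxel centers at
`(index + 0.5)·spacing`. File I/O (NIfTI, MetaImage) goes through
SimpleITK, whose (Z, Y, X) array view maps directly onto this convention.

## Synthetic phantoms

The clinical cohort this task comes from is private, so every experiment
runs on synthetic neurovascular phantoms that reproduce its *structural*
character on the (32, 96, 96) working grid at 1 mm spacing:

* brainstem: an ellipsoid (semi-axes ≈ 14×22×16 mm, ~7% of the volume);
* vessels: three polyline tubes (radius 1.6–2 mm) emulating a basilar
  trunk and two lateral branches, rasterized by exact point-to-segment
  distance (a capsule sweep, so tube joints are smooth);
* trigeminal nerve: a 1.2 mm-radius tube lying almost in-plane near the
  brainstem surface, spanning 3 consecutive axial slices and ~0.03% of the
  voxels; generation fails loudly if a configured nerve exceeds 4 slices;
* intensities: per-tissue Gaussian texture around ordered means
  (background 60 < brainstem 110 < nerve 140 < vessels 200, arbitrary
  units) plus global additive Gaussian noise (σ = 10). These contrasts are
  free parameters, chosen to make segmentation nontrivial but learnable;
  they are not claims about real MRA tissue statistics.
* optional contact geometry: the last vessel is diverted to pass within
  ~1 voxel of the nerve midpoint, emulating NVC where boundary refinement
  matters.

Label precedence at overlaps is nerve > vessel > brainstem > background,
so the nerve root "entering" the brainstem stays nerve-labelled. Cohorts
(`make_dataset`) jitter control points (±1.5 mm in-plane, nerve axial
jitter kept small to preserve the 3-slice extent), radii (±10%), ellipsoid
pose and intensities, and are bit-reproducible from a seed.

What the phantoms do **not** model: MR flow/TOF physics, bias fields,
bifurcating vascular trees, partial-volume fuzz at boundaries, or
inter-subject anatomical variability beyond geometric jitter. Passing the
end-to-end tests therefore demonstrates that the architecture, loss,
pipeline and metrics work as specified — not clinical-grade accuracy on
real MRA.

## Evaluation metrics

Per foreground class: DSC; Hausdorff distance (max of the two directed
max–min distances between surface voxel centers); and average surface
distance (symmetric mean nearest-surface distance). Surfaces are
foreground voxels with a background 6-neighbour, with out-of-grid
treated as background; distances are Euclidean in physical mm via the
spacing, computed with an exact distance transform and verified against
exhaustive pairwise search. Conventions: both-empty DSC = 1, one-empty
DSC = 0, HD/ASD undefined (NaN in reports) when a class is missing.
Distances between voxel centers are reported as raw mm — no sub-voxel
meshing and no normalization. A DSC above 0.70 is flagged as "excellent
agreement" in reports, following the usual reading of that threshold.

## Training protocol

Adam (initial LR 0.001, weight decay 0.0005 as an L2 term), poly schedule
`lr = base·(1 − step/max_steps)^0.9`, capped at `max_iterations` optimizer
steps (interpreted as steps, not epochs; both supported via
`iteration_unit`), default batch size 2 (single volumes accumulated).
Model selection keeps the checkpoint with the best mean foreground DSC on
the held-out fold of the cross-validation round; evaluation happens every
`eval_every` steps, with optional patience-based early stopping and an
optional target-DSC stop, both within the iteration cap. 5-fold
cross-validation over a 50-case cohort (10 held out per round) is the
default split. Runs are fully seeded and bit-reproducible; a NaN loss
aborts with a diagnostic snapshot.

## Scaled CPU study sizes

The package is exercised end to end on one CPU, so the learning tests and
the acceptance script use deliberately reduced problem sizes, chosen once:

* training phantoms on a (16, 48, 48) grid (half-scale in-plane geometry,
  nerve radius kept at 1.2 mm so it still spans 3 slices);
* width-8 cascade (coarse base width 8, depth 2; refiner width 8, depth 2);
* overfit check: 2 phantoms, ≤ 300 steps, stop once training brainstem
  DSC ≥ 0.8;
* generalization check: 10 phantoms, 2-fold cross-validation, ≤ 300 steps
  per fold with patience-4 early stopping; held-out brainstem DSC is
  compared against the 0.70 excellent-agreement level;
* ablation trend: 3 seeds × 3 arms on (16, 40, 40) contact phantoms
  (4 train / 2 test, 200 steps), comparing per-seed mean held-out
  trigeminal-nerve DSC orderings. The arms use base width 12 so the
  multi-scale blocks get 3-channel subsets; at width 8 the 2-channel
  subsets structurally handicap them and the comparison stops being about
  the block design.

At these sizes the vessel and especially nerve classes are *not* expected
to reach their large-scale accuracy; the brainstem threshold and the
ablation ordering are the quantities the scaled runs assert. The nerve
class in particular is ~30 voxels per case here, so its held-out DSC is
high-variance and the ablation ordering check is a weak, noisy signal.

## Numerical choices and edge cases

* Softmax produces the confidence map (the probabilization function is a
  package choice); logs are clamped at 1e-12.
* Batch norm in both stages, momentum 0.1; eval mode uses running stats.
* Kaiming-style init for convolutions, zero biases, seed-controlled;
  attention scalars start at 0 (identity attention).
* Max-pool halves each axis (inputs validated for divisibility by
  2^depth); upsampling is nearest-neighbour.
* The 1×1×1 convolution before the Res2 split keeps the channel count.
* Degenerate inputs error early and name the offender: identical tube
  control points, oversized radii, labels outside {0..3}, non-normalized
  probabilities, empty masks in surface metrics.

## Known limitations

* The engine is CPU-bound; volumes much beyond the working crop or widths
  beyond ~32 are slow to train.
* Nearest-neighbour upsampling plus shallow refiner depth trades a little
  boundary fidelity for runtime.
* The attention module's spatial affinity is quadratic in bottleneck
  voxels; keep `depth` ≥ 2 for large grids.
* Phantom realism limits transfer claims to real MRA (see above).
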