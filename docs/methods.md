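# Methods

This note documents the models and procedures implemented in `phenoseg`, the
assumptions behind them, and the choices made where the design was genuinely
open.

## Problem setting

Organ-level semantic segmentation of 3D crop point clouds: every point of a
scanned plant is classified as **leaf (0)** or **stem (1)**. Clouds from
multi-view reconstruction are large (10^4–10^6 points) and strongly
non-uniform — foliage is dense, stems are thin and sparse, and late-growth
canopies self-occlude. The toolkit addresses two coupled problems: choosing
*which* points to keep when down-sampling (the budget should depend on the
plant's structural complexity) and labeling them with a network whose
receptive fields respect plant geometry.

All coordinates are meters; plant height is the z-extent of the bounding box.

## Adaptive two-stage down-sampling (DMSS)

Stage 1 keeps a uniform random 10 % of the points. Stage 2 runs
farthest-point sampling (FPS) on that subset at a ratio computed from two
dispersion statistics of the **original** cloud:

- voxel-occupancy variation, on a 5 cm grid anchored at the bounding-box
  minimum corner, over occupied voxels only, with population SD:
  `CV_v = sigma_N / mu_N`, weight `w_v = 1 / (1 + CV_v)`;
- local-density variation with `rho_i = k / sum_{j in kNN(i)} ||p_i - p_j||^2`
  (k = 50, self excluded): `CV_d = sigma_rho / mu_rho`, weight
  `w_d = CV_d / (CV_v + CV_d)`.

The FPS ratio is `r_FPS = r_base (w_v + lambda w_d)` with defaults
`r_base = lambda = 0.5`, and the overall retained fraction
(`0.10 * r_FPS`) is clamped to [2 %, 8 %]. A weighted sum
`C_joint = lambda CV_v + (1 - lambda) CV_d` is reported as a diagnostic only;
only the `(w_v, w_d)` rule determines the budget, because only it is tied to
a ratio by construction.

Numerical conventions: statistics on the original cloud (stable across
stage-1 seeds); FPS breaks argmax ties toward the lowest index and takes its
start point from the seed (or an explicit `start`); duplicated points are
guarded by flooring the neighbor distance sum at 1e-300. The reciprocal
density reading `rho = sum d^2 / k` is available via
`DMSSParams(reciprocal_density=True)`.

Note the rule's direction: `w_v` *decreases* with occupancy unevenness while
`w_d` increases with density unevenness, so which clouds receive larger
budgets depends on which statistic grows faster. On the bundled generator the
density CV of late-growth plants outpaces their voxel CV, so mature canopies
retain a larger fraction than seedlings — the behavior the adaptive rule
exists to produce.

## ISS keypoints and the retention benchmark

Intrinsic Shape Signatures: per point, the covariance of neighbors within
`salient_radius` is eigen-decomposed (`l1 >= l2 >= l3`, unweighted
covariance); candidates satisfy `l2/l1 < 0.975` and `l3/l2 < 0.975`; greedy
non-maximum suppression on `l3` within `nms_radius` (descending saliency,
ties to the lower index). Defaults tie the radii to the cloud's mean
nearest-neighbor spacing (6x / 4x) with `min_neighbors = 5`.

A sampler is scored by the fraction of keypoints that have a sampled point
within a tolerance `epsilon`. The benchmark default is
`epsilon = 1.5 * spacing / sqrt(retained_fraction)` — 1.5x the expected
spacing of the sampled subset — so a keypoint counts as retained when the
sample represents it at the sample's own resolution. With a fixed small
`epsilon` (e.g. 2x the original spacing) retention at 2–8 % budgets is
pinned near `(epsilon / sample_spacing)^2` ≈ 0.1 for every method, which is
uninformative; the resolution-matched tolerance produces retention levels
around 0.7–0.95 and cleanly separates spatially uniform samplers from random
sampling. Wall-clock timings in the report are informational only.

## Segmentation network

An encoder–decoder over the point set. Input features are the centered,
height-normalized coordinates, linearly embedded. Each encoder stage applies:

1. **Multi-scale aggregation**: ball neighborhoods at radii
   {0.05, 0.10, 0.15} x plant height (<= 32 neighbors, nearest first, self
   always included; an empty ball falls back to the self point). Messages
   `phi_s([f_j - f_i; psi_ij])` use a two-layer shared MLP per scale and a
   learned positional embedding `psi_ij` of the height-normalized offset and
   its norm (two-layer MLP, width 8). Messages are combined by an
   attention-weighted sum with the distance kernel below; the per-scale
   outputs are concatenated.
2. **Geometry-aware attention**: over k = 16 nearest neighbors, weights
   `a_ij = softmax_j(-d_ij / sigma)`, attended feature `sum_j a_ij f_j` (raw
   neighbor features, per the formulation), followed by the block's linear
   projection. `sigma` defaults to the stage's effective mid radius
   (`sigma_mode="radius"`), keeping the weights scale-free; a fixed scalar is
   available.
3. **Fusion**: concatenation of the two branches, linear map `W_f`, ReLU.
4. **TransitionDown**: FPS to 25 % of the points, features max-pooled over
   each support point's mid-radius ball after a pointwise linear+ReLU map.

The decoder interpolates coarse features onto the finer level with
inverse-square-distance weights over the 3 nearest coarse points
(regularizer 1e-8; a coincident point recovers the coarse feature),
concatenates the skip features, applies a linear+ReLU, and refines with the
same geometry-attention block. The head is linear–ReLU–linear to 2 classes.

FPS inside the network starts from the lexicographically smallest point, so
inference is deterministic and stable under permutation of the input order
(up to exact distance ties). Height-normalizing both the radii and the
positional-embedding inputs makes the forward pass invariant to rigid
translation and uniform scaling.

Ablation switches: `no_multiscale` uses only the mid radius;
`no_geometry_attention` replaces the attention blocks with unweighted mean
aggregation (dropping their projections, hence strictly fewer parameters);
`baseline_pt` is a two-layer scalar dot-product self-attention network
(`q = W_q x`, `k = W_k x`, `v = W_v x`; per-neighborhood softmax of `q.k`)
over KNN neighborhoods.

The network runs on a small reverse-mode autodiff core over numpy
(`phenoseg.autograd`): dense linear maps, ReLU, concatenation, gathers, and
segment reductions (weighted sum, softmax, max — max gradients split equally
among ties), in float64 on one CPU core. Channel widths, stage count and
neighborhood caps are configuration, not claims; the defaults
([32, 64, 128, 256], 4 stages) suit larger clouds, while the bundled
training harness uses a 2-stage [24, 32] model.

## Training and evaluation

Weighted cross-entropy (inverse-frequency class weights by default — stems
are the minority class; uniform available) minimized with AdamW (lr 0.003,
weight decay 0.01, batch size 2 by gradient accumulation), cosine
learning-rate decay (step decay optional), early stopping on validation loss
(patience 20 epochs, min-delta 1e-4 — read as a plain threshold, not a
statistical test), best-validation checkpoint returned. Everything is seeded.

Augmentations (per batch, seeded): a single rigid translation drawn from
[-0.5, 0.5] m per axis; isotropic scaling about the centroid by a factor in
[0.8, 1.2]; a mirror flip through the XZ plane at probability 1/2. None
changes labels, point count, or order.

Metrics per class (one-vs-rest): `Acc = (TP + TN) / N`,
`IoU = TP / (TP + FP + FN)`; `mIoU` and `mAcc` are the means over the leaf
and stem classes, reported as percentages. A class absent from both truth and
prediction has vacuous IoU 100 (with a warning). The cross-cloud aggregate is
the unweighted mean over clouds.

Splits: `holdout_cultivar` reserves one cultivar's full cycle for test and a
second for validation; `holdout_plant` does the same by plant id.

## Synthetic plant generator

The generator produces labeled clouds with the statistical structure the
method is sensitive to, not photorealistic plants. Stems and branches are
tubes around mildly wandering polylines; leaves are quadratically bent
ellipse patches — trifoliate triples for the soybean-like crop, long arched
blades for maize-like, five-leaflet clusters for tomato-like. The growth
stage (1–12) linearly drives height from 0.15 m to 1.20 m and monotonically
increases node count, leaf size and canopy overlap. Cultivars differ by
systematic height (±7 %) and leaf-size (±10 %) offsets.

Density structure, the part that matters for the sampler: surface sampling
density emulates a scanning budget. Early stages are close-range scans (leaf
density up to ~6x the nominal `points_per_area`, 40 000 pts/m² by default),
late stages are captured coarser but with growing per-leaf variability
(log-normal multipliers, mean-corrected) and, from stage 7 on, dense pod
clusters at stem nodes — small spheroids sampled at ~24x nominal density,
the reproductive-stage analogue of geometrically tight structures. These
mechanisms make the KNN-density CV grow from ≈0.37 (stage 1) to ≈2.5
(stage 12) while the voxel CV grows more slowly, which is what lets the
adaptive sampler allocate larger budgets to mature plants. Occlusion removes
a fraction (default 0.15) of points hidden from a random side viewpoint via
a 1° spherical-bin nearest-surface test. Gaussian coordinate noise
(sd 1 mm) is added last. Generation is byte-deterministic per spec+seed.

What the generator does **not** emulate: real reconstruction artifacts
(ghost surfaces, registration error), color/reflectance, petioles as
separate organs, fine leaf serration, and sub-0.2 mm resolution. Tests that
pass on these clouds show the pipeline reacts correctly to two-class organ
geometry and non-uniform density; they do not certify accuracy on scanned
field data.

## Harness scales

The bundled checks run on one CPU core at deliberately small problem sizes:
FPS oracle comparisons on clouds of up to 64 points; clamp compliance on
~100 plants at 6 000 pts/m²; the retention benchmark on 20 late-stage plants
at 8 000 pts/m² (≈3–9 k points each); the learning checks on ten ~220-point
early-stage plants with the 2-stage [24, 32] model (overfit to 95 % train
mAcc, median of 3 seeds; ablation comparison at 35 epochs). These sizes are
the package's desk-scale defaults; all of them are parameters.

## Known limitations

- Training is CPU-bound numpy; it is meant for method verification at desk
  scale, not for full-size benchmark clouds. No mixed precision.
- The ISS implementation loops over points in Python for the covariance
  step; fine up to ~10^4-point clouds, slow beyond.
- The ratio rule inherits the formulation's asymmetry (`w_v` caps the budget
  of uneven-occupancy clouds); on data whose voxel CV dominates, complex
  clouds receive *smaller* budgets.
- Binary labels only; no instance segmentation.
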