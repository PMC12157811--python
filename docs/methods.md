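# Methods

This note documents the models, parameters and numerical choices behind
`cottonphen`, and what the synthetic benchmark does and does not establish.

## Problem setting

A single cotton plant is observed as an unordered 3D point cloud (meters).
The pipeline stages are: (1) depth filtering to strip background, (2) growth
period classification (periods 1–4, defined by the organ inventory: 3, 4, 5,
and 6 organ types respectively), (3) per-point organ segmentation into five
classes (leaf 0, stem/petiole 1, main stem 2, bud 3, boll 4), (4) instance
segmentation of one class into individual organs, and (5) phenotype
extraction: plant height H, main-stem path length Lstem, and the shedding
rate (I − E)/I × 100 %, with I the peak bud census and E the boll count at
maturity.

## Preprocessing

**Depth filter.** The single-axis depth threshold Dmin ≤ D_P ≤ Dmax is
generalized to an axis-aligned box with closed intervals on x, y and z,
since in practice all three axis ranges are limited to isolate the plant.
The filter is idempotent and decidable per point.

**Normals and curvature.** k-neighborhood PCA (default k = 30). The normal
is the eigenvector of the smallest covariance eigenvalue; curvature is the
surface variation λ₀/(λ₀+λ₁+λ₂) ∈ [0, ⅓] — bounded, which makes curvature
thresholds transferable across scales. Normals are unoriented (no viewpoint
is available); every consumer uses absolute angles. Sign is fixed
deterministically (largest component positive) so runs are reproducible.
Coincident neighborhoods fall back to curvature 0 and an arbitrary unit
normal with a logged warning.

**Sampling and augmentation.** Fixed-size sampling is uniform without
replacement (with replacement when the cloud is smaller than the target, to
keep the fixed-size contract). Augmentations: Gaussian displacement with one
σ drawn per cloud from [0.02, 0.05] m applied i.i.d. per point and axis
(per-cloud σ models a per-acquisition error level); rigid rotation about the
vertical axis through the centroid, angle uniform in [0°, 180°], normals
co-rotated; per-point uniform jitter with amplitude drawn from [0, 0.05] m.
Noise augmentations perturb coordinates only.

## Segmentation network

Input is a sampled cloud with 6 channels (x, y, z, nx, ny, nz). Labels are
deliberately excluded from the features — they are the supervision target.
Horizontal coordinates are centered on the centroid; z is referenced to the
lowest point, so height-along-plant is a usable cue for separating stem from
main stem.

The static kNN graph (k = 20, built once per forward pass on input
coordinates) feeds an edge convolution with the additive two-term edge
feature e_ij = φ(θ·(x_i − x_ij)) + ψ(θ′·x_ij), where x_ij is the neighbor's
feature vector, φ = ψ = LeakyReLU(0.2), and aggregation over the k edges is
a channel-wise max. Rebuilding the graph in feature space is intentionally
not done: the variant implemented here defines the graph on coordinates.

Widths (chosen as defaults; the architecture description leaves them open):
edge conv 6→64, pointwise conv 64→64, residual blocks 64→128 and 128→256,
fusion of all intermediates plus a replicated per-cloud global max feature
(64+64+128+256+256 = 768), head 768→256→128→5. Each residual block runs two
paths — 1×1 conv → BN → LeakyReLU, and 1×1 conv → BN — fused by addition and
a final LeakyReLU. Batch normalization keeps running statistics; training
and inference modes are switched explicitly.

**Training.** Adam with decoupled weight decay; defaults: weight decay 0.01,
learning rate 0.001 (constant), 200 epochs, batch size 2, 2048 sample
points, unweighted cross-entropy (class weighting available in config).
Each plant contributes `resamples_per_cloud` (default 2) independent
fixed-size draws per run, and an optional per-step random rotation of the
feature channels about the vertical axis (cheap, exact under the static
graph because rotation is an isometry). Runs are deterministic given the
seed. The period classifier is a pointwise MLP (6→32→64) with global max
pooling and a fully connected head (64→32→4), trained full-batch.

**Inference on arbitrary clouds.** The cloud is sampled to the network size,
normals are estimated *on the sample* (matching the training-time feature
scale — estimating them on the dense cloud first measurably degrades
accuracy), and predictions propagate to all points via the nearest sampled
neighbor.

## Instance segmentation (improved region growing)

Within one semantic class, with normals/curvature estimated on that class
subset only (neighborhood 16, kept below the inter-blade clearance so
neighborhoods do not straddle adjacent organs):

1. **Gated growth.** Seeds are taken in ascending curvature order (ties →
   lower index; a seed must itself pass the curvature gate, or be a
   candidate promoted in a previous region's growth). The frontier expands
   through spatial kNN adjacency (default 10): a neighbor joins if the angle
   between its normal and the *seed's* normal is < θ and its curvature is
   < k; a neighbor passing the normal gate but failing curvature becomes a
   candidate seed for a later region; a neighbor failing the normal gate is
   not grown. Membership is a closure, so the result is independent of
   traversal order.
2. **Point-distance mapping.** Every remaining unprocessed point is absorbed
   into the region with the nearest member point (single linkage), closest
   point first, with the distance map updated as points are absorbed.
3. **Noise filter.** Regions below `min_region_points` are dissolved; their
   points are reassigned by the step-2 rule (or marked noise when merging is
   disabled). At most N regions are returned.

The plain baseline runs step 1 only; whatever fails the gates stays
unsegmented — exactly the residue (small, strongly curved young leaves) the
improvement eliminates.

Defaults for blade-like organs: θ = 30°, k = 0.05, min_region_points = 30,
N = 64, adjacency 10 — set once on synthetic fixtures and exposed in config.
For compact blob organs (buds, bolls) the gates are irrelevant — an
ellipsoid has no smooth interior plane — so `BLOB_PARAMS` loosens them
(θ = 90°, k = 0.9, min 15 points) and lets spatial adjacency separate
organs. Color-based gating is deliberately absent: organ points of the same
class are nearly color-identical, so color adds no separating power here.

## Phenotypes

**Pot-plane alignment.** A consensus plane (RANSAC, 200 deterministic
trials, 5 mm inlier band) is fitted to the lowest decile of points, followed
by one refit on inliers within 2.5 mm, which sheds stem-base points caught
in the coarse band. The rigid rotation mapping the plane normal to +z is
applied about the plane centroid; distances are preserved exactly.

**Height.** H = Zmax − Zmin over plant points; background/pot points
(label −1) are excluded when labels exist.

**Stem length.** The accumulated Euclidean distance needs an ordering of the
main-stem points. The points are projected on their principal axis (oriented
upward), binned at 1 cm, and the polyline through bin centroids is
accumulated. Binning collapses the cylinder girth so the surface scatter is
not double-counted; 1 cm is small against stem curvature (closed-form helix
tests recover arc length within 2 %) and large against point spacing.

**Shedding rate.** Reported both as the exact real and as an integer percent
truncated toward zero (66.67 → 66), matching the convention of per-plant
shedding tables. I counts bud+boll instances at the bud-stage acquisition;
E counts boll instances at the final acquisition, clamped to ≤ I.

## Metrics

IoU_i = TP/(TP+FP+FN) per class; mIoU averages over classes present in the
ground truth by default (early periods have no buds/bolls; penalizing absent
classes conflates staging with segmentation), with an "all" mode available.
Precision/recall/F1 are macro-averaged; zero-denominator classes score 0
with a warning. MRE applies absolute values — a signed mean would cancel
errors and not be a relative error. Count regression reports R² and RMSE.
Points with true label −1 (background) are excluded from all denominators.

## Synthetic benchmark

The generator emulates the structural regime of greenhouse cotton: a gently
curved swept-cylinder main stem (waviness 3 % of height), petioles branching
at golden-angle azimuths, superellipse leaf blades with parabolic bending
(max normal deviation ≈ 17°, safely inside the 30° gate), buds/bolls as
ellipsoids on short stalks with non-interpenetration enforced, uniform
outliers labeled −1, and period-typical organ counts (3–8 leaves in period
1, 20–30 around the bud stage, heights 0.15–0.8 m). A stated fraction of
leaves is placed in overlapping pairs: the partner blade is stacked along
the first blade's normal with ≈ 5 mm closest approach and a normal tilted
0.6–0.8 rad — overlapping in projection, separated by less than typical leaf
spacing, and beyond the normal gate.

What it does not emulate: sensor-specific noise spectra, color/texture,
missing data from self-occlusion, wind deformation, and real morphological
variety (lobed leaf outlines, fused canopies). Passing the benchmark
therefore shows the algorithms are correctly implemented and recover known
structure under controlled overlap and noise — not that the reported
accuracy transfers to field scans.

**Desk-scale study conditions.** The learning benchmark uses 20 plants
(16 train / 4 held out, mixed periods), 512 sample points, 50 epochs, 3
resamples per cloud, one CPU — sizes chosen so a full run of the suite
remains a desk-scale exercise. Held-out evaluation is at the network's
native sampling resolution. The count-regression benchmark runs the
improved region growing on the leaf points of all 20 plants.

## Numerical choices and edge cases

- kNN graphs: brute-force exact with stable argsort (ties → lower index) up
  to 2500 points, kd-tree beyond (ties there follow the tree's order; random
  real coordinates make ties measure-zero).
- Region-growing determinism: seed order is curvature-sorted with index
  tie-break; step-2 absorption is ascending-distance with index tie-break.
- Degenerate inputs: empty clouds are legal for filtering and instance
  labeling; single points have height 0; stem length requires ≥ 2 skeleton
  bins; a collinear pot base raises instead of fitting a pseudo-plane.
- Checkpoints are single `.npz` files with a JSON metadata header and a
  format version.

## Known limitations

- The network is a CPU numpy implementation: practical for desk-scale
  experiments (minutes for the benchmark above), not for 200-epoch runs on
  hundreds of 2048-point clouds.
- Period classification uses global geometry (size, organ presence); it does
  not implement multi-scale set abstraction.
- Main-stem length assumes a single dominant axis; strongly forked or
  prostrate stems would need a graph skeleton instead of axis binning.
- The shedding rate compares two acquisitions by census, not by tracking
  individual buds through time.
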