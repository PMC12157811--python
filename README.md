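# cottonphen

3D phenotyping of cotton plants across the full growth period, from single-plant
point clouds: depth-filtered preprocessing, deep organ segmentation, single-organ
instance segmentation, and extraction of plant height, main-stem length and the
shedding (bell-drop) rate.

## Who this is for

Plant-phenotyping researchers who reconstruct individual cotton plants as 3D
point clouds (photogrammetry, NeRF, laser scanning) and need organ-level
measurements without destructive manual calipers. Cotton is the hard case for
such pipelines: across its four growth periods (seedling, bud stage, early and
late boll stage) the organ inventory grows from three classes (leaf, stem, main
stem) to five (plus buds and bolls), and mature plants have 20–30 severely
overlapping leaves.

## What's inside

- **`pointcloud_core`** — the `LabeledPointCloud` container (coords in meters,
  unit normals, surface-variation curvature, organ labels 0=leaf, 1=stem,
  2=mainstem, 3=bud, 4=boll, −1=background), PLY/PCD/ASCII I/O, axis-aligned
  depth filtering (keep exactly the points with Dmin ≤ D_P ≤ Dmax on each
  axis), PCA normal/curvature estimation, fixed-size sampling, and the three
  training augmentations (Gaussian noise with per-cloud σ ∈ [0.02, 0.05] m,
  rotation about the vertical axis uniform in [0°, 180°], per-point jitter
  bounded by [0, 0.05] m).
- **`resdgcnn`** — a dynamic-graph convolution segmentation network with
  residual blocks. On a kNN graph (k = 20) the edge feature of edge (i, j) is
  the additive two-term form
  `e_ij = φ(θ·(x_i − x_ij)) + ψ(θ′·x_ij)`
  with leaky-rectifier activations, aggregated per point by a channel-wise
  max. Two two-path residual blocks (1×1 conv → BN → LeakyReLU fused with
  conv → BN by addition) follow, then multi-scale feature fusion with a
  replicated global max-pooled feature and a pointwise head to 5 per-point
  class logits. A lightweight pointwise-MLP + global-max-pool classifier
  predicts the growth period. Implemented on a small in-repo reverse-mode
  autodiff engine over numpy (`cottonphen.nn`).
- **`region_growing`** — improved region growing for instance segmentation of
  one organ class: seeds in ascending curvature order, growth gated by a
  normal-angle threshold θ and a curvature threshold k, then a point-distance
  mapping step that absorbs every unprocessed point into the nearest region
  (closest first, with live distance-map updates), and a small-region noise
  filter. The plain baseline (step 1 only) is included for ablation.
- **`phenotypes`** — pot-plane alignment, plant height `H = Zmax − Zmin`,
  main-stem path length `Lstem = Σ‖p_{i+1} − p_i‖` over a height-binned
  centroid skeleton, and the shedding rate
  `rate = (I − E)/I × 100 %`,
  where I is the peak bud census and E the count surviving to boll maturity
  (reported exactly and as an integer percent truncated toward zero).
- **`evaluation`** — per-class IoU/mIoU, macro precision/recall/F1, mean
  relative error, and count-regression R²/RMSE.
- **`synthetic_cotton`** — a parametric generator of labeled single-plant
  clouds for all four periods with exact ground truth (labels, instance ids,
  height, stem arc length, organ counts), including controlled leaf overlap —
  the regime the improved region growing targets.
- **`cli`** — `cottonphen` with subcommands `synth`, `train`, `segment`,
  `instances`, `phenotype`, `evaluate`, `pipeline`.

## Worked example

Generate five bud-stage plants and measure the first one:

```sh
$ cottonphen synth --n 5 --period-mix "2:1" --seed 7 --out plants
wrote 5 plants to plants (4 train / 1 test)

$ cottonphen instances --in plants/plant_0000.ply --use label \
      --out inst.ply --report counts.csv
leaf: 30 instances -> inst.ply

$ cottonphen phenotype --in plants/plant_0000.ply --report pheno.csv
H=0.5274 m, Lstem=0.5344 m, buds=6, bolls=0 -> pheno.csv
```

The manifest records the generating truth for this plant: height
0.52742 m, main-stem arc length 0.53485 m, 30 leaves, 6 buds. The measured
height matches exactly (the generator is noiseless), the accumulated stem
length is within 0.1 %, and both the 30 leaf instances and the 6 buds are
recovered exactly by region growing — leaf counting feeds the shedding-rate
and leaf-census figures.

With a trained checkpoint (`cottonphen train --manifest plants/manifest.csv
--out model.npz`), `cottonphen pipeline --in plant.ply --weights model.npz
--out-dir out/` runs period classification → organ segmentation → instance
segmentation → phenotype extraction and writes `classes.ply`,
`instances.ply` and `phenotypes.csv` with the configuration hash and seed in
every output.

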