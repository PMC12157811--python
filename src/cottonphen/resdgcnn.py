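"""ResDGCNN: graph-convolution organ segmentation with residual blocks.

The network ingests a fixed-size sampled cloud with 6 input channels
(x, y, z, nx, ny, nz), builds a k-nearest-neighbor graph on the coordinates,
and stacks: an edge convolution whose edge feature is the additive two-term
form  e_ij = phi(theta . (x_i - x_j)) + psi(theta' . x_j)  aggregated by a
channel-wise max over the k edges; a shared pointwise convolution; two
two-path residual convolution blocks (1x1 conv + BN + LeakyReLU on one path,
conv + BN on the other, fused by addition); and a fusion head that
concatenates all intermediate per-point features with a replicated global
max-pooled feature before pointwise layers down to the 5 organ logits.

A lightweight pointwise-MLP + global-max-pool classifier predicts the growth
period (1..4) for the staging step of the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import nn
from .pointcloud_core import (LabeledPointCloud, PointCloudError,
                              estimate_normals_curvature, sample_fixed)


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def knn_graph(coords: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest neighbors of each point, self excluded.

    Exact: full pairwise distances with a stable argsort, so ties are broken
    by the lower point index.  Requires N > k.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = len(coords)
    if n <= k:
        raise PointCloudError(f"knn_graph needs N > k, got N={n}, k={k}")
    if n <= 2500:
        # exact pairwise distances + stable argsort (tie -> lower index)
        d2 = np.sum((coords[:, None, :] - coords[None, :, :])**2, axis=2)
        np.fill_diagonal(d2, np.inf)
        return np.argsort(d2, axis=1, kind="stable")[:, :k]
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)
    # drop the self match from each row (not always the first at duplicates)
    rows = np.arange(n)
    is_self = idx == rows[:, None]
    no_self = ~is_self.any(axis=1)
    if no_self.any():                  # duplicated coords: drop the last
        is_self[no_self, k] = True
    return idx[~is_self].reshape(n, k)


# ---------------------------------------------------------------------------
# specs and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeConvSpec:
    in_channels: int
    out_channels: int
    k: int = 20
    activation_slope: float = 0.2

    def __post_init__(self):
        if self.k < 1:
            raise PointCloudError("k must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Training defaults: weight decay 0.01, lr 0.001, 200 epochs, batch 2,
    2048 sample points, 6 input channels, 5 classes, k=20 neighbors."""

    weight_decay: float = 0.01
    learning_rate: float = 0.001
    epochs: int = 200
    batch_size: int = 2
    n_points: int = 2048
    input_channels: int = 6
    n_classes: int = 5
    k: int = 20
    rng_seed: int = 0
    class_weights: tuple | None = None   # optional CE reweighting
    resamples_per_cloud: int = 2         # independent fixed-size draws per plant
    rotation_augment: bool = True        # random z-rotation of features per step

    def __post_init__(self):
        for name in ("weight_decay", "learning_rate", "epochs", "batch_size",
                     "n_points", "input_channels", "n_classes", "k"):
            if getattr(self, name) <= 0:
                raise PointCloudError(f"{name} must be positive")


@dataclass
class SegmentationResult:
    class_logits: np.ndarray          # (N, C)
    class_pred: np.ndarray            # (N,)
    period_pred: int | None = None

    def __post_init__(self):
        if not np.array_equal(self.class_pred, self.class_logits.argmax(axis=1)):
            raise PointCloudError("class_pred inconsistent with logits argmax")


# ---------------------------------------------------------------------------
# network modules
# ---------------------------------------------------------------------------

class EdgeConv(nn.Module):
    """Edge convolution with additive two-term edge features, max-aggregated."""

    def __init__(self, spec: EdgeConvSpec, rng: np.random.Generator):
        self.spec = spec
        self.theta = nn.Linear(spec.in_channels, spec.out_channels, rng)
        self.theta_prime = nn.Linear(spec.in_channels, spec.out_channels, rng)

    def __call__(self, x: nn.Tensor, neighbor_indices: np.ndarray) -> nn.Tensor:
        n, k = neighbor_indices.shape
        if x.shape[0] != n:
            raise PointCloudError("features and neighbor_indices misaligned")
        xj = x.gather_rows(neighbor_indices)                          # (N,k,C)
        xi = x.gather_rows(np.broadcast_to(np.arange(n)[:, None], (n, k)))
        s = self.spec.activation_slope
        e = (nn.leaky_relu(self.theta(xi - xj), s)
             + nn.leaky_relu(self.theta_prime(xj), s))
        return e.max(axis=1)                                          # (N,Cout)


class ResidualBlock(nn.Module):
    """Two-path residual convolution block.

    Path A: 1x1 conv -> BN -> LeakyReLU; path B: 1x1 conv -> BN.  The paths
    are fused by addition and passed through a final LeakyReLU.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, slope: float = 0.2):
        self.conv_a = nn.Linear(in_channels, out_channels, rng)
        self.bn_a = nn.BatchNorm(out_channels)
        self.conv_b = nn.Linear(in_channels, out_channels, rng)
        self.bn_b = nn.BatchNorm(out_channels)
        self.slope = slope

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        a = nn.leaky_relu(self.bn_a(self.conv_a(x)), self.slope)
        b = self.bn_b(self.conv_b(x))
        return nn.leaky_relu(a + b, self.slope)


class ResDGCNN(nn.Module):
    """The full segmentation network; see the module docstring for the stack."""

    WIDTHS = (64, 64, 128, 256)      # edge conv, pointwise conv, res1, res2
    HEAD = (256, 128)

    def __init__(self, in_channels: int = 6, n_classes: int = 5, k: int = 20,
                 rng_seed: int = 0):
        rng = np.random.default_rng(rng_seed)
        w1, w2, w3, w4 = self.WIDTHS
        self.in_channels, self.n_classes, self.k = in_channels, n_classes, k
        self.edge = EdgeConv(EdgeConvSpec(in_channels, w1, k=k), rng)
        self.bn_edge = nn.BatchNorm(w1)
        self.conv1 = nn.Linear(w1, w2, rng)
        self.bn1 = nn.BatchNorm(w2)
        self.res1 = ResidualBlock(w2, w3, rng)
        self.res2 = ResidualBlock(w3, w4, rng)
        fused = w1 + w2 + w3 + w4 + w4          # intermediates + global feature
        h1, h2 = self.HEAD
        self.head1 = nn.Linear(fused, h1, rng)
        self.bn_h1 = nn.BatchNorm(h1)
        self.head2 = nn.Linear(h1, h2, rng)
        self.bn_h2 = nn.BatchNorm(h2)
        self.head3 = nn.Linear(h2, n_classes, rng)
        self.training = True

    def forward(self, features: np.ndarray, neighbor_indices: np.ndarray,
                segment_ids: np.ndarray | None = None,
                n_segments: int = 1) -> nn.Tensor:
        """Per-point logits for stacked clouds.

        ``segment_ids`` assigns each row to its cloud so the global max pool
        does not mix plants in a batch; neighbor indices must already be
        offset into the stacked feature rows.
        """
        if segment_ids is None:
            segment_ids = np.zeros(len(features), dtype=np.int64)
        x = nn.Tensor(features)
        f1 = nn.leaky_relu(self.bn_edge(self.edge(x, neighbor_indices)), 0.2)
        f2 = nn.leaky_relu(self.bn1(self.conv1(f1)), 0.2)
        f3 = self.res1(f2)
        f4 = self.res2(f3)
        g = nn.segment_max(f4, segment_ids, n_segments)       # (B, w4)
        g_rep = g.gather_rows(segment_ids)                    # (N, w4)
        h = nn.concat([f1, f2, f3, f4, g_rep], axis=-1)
        h = nn.leaky_relu(self.bn_h1(self.head1(h)), 0.2)
        h = nn.leaky_relu(self.bn_h2(self.head2(h)), 0.2)
        return self.head3(h)


class PeriodClassifier(nn.Module):
    """Pointwise MLP + global max pool + fully connected period head."""

    def __init__(self, in_channels: int = 6, n_periods: int = 4, rng_seed: int = 0):
        rng = np.random.default_rng(rng_seed)
        self.in_channels, self.n_periods = in_channels, n_periods
        self.fc1 = nn.Linear(in_channels, 32, rng)
        self.fc2 = nn.Linear(32, 64, rng)
        self.fc3 = nn.Linear(64, 32, rng)
        self.fc4 = nn.Linear(32, n_periods, rng)
        self.training = True

    def forward(self, features: np.ndarray, segment_ids: np.ndarray,
                n_segments: int) -> nn.Tensor:
        x = nn.Tensor(features)
        h = nn.leaky_relu(self.fc1(x), 0.2)
        h = nn.leaky_relu(self.fc2(h), 0.2)
        g = nn.segment_max(h, segment_ids, n_segments)
        g = nn.leaky_relu(self.fc3(g), 0.2)
        return self.fc4(g)


# ---------------------------------------------------------------------------
# feature preparation and inference
# ---------------------------------------------------------------------------

def cloud_features(cloud: LabeledPointCloud) -> np.ndarray:
    """6-channel input features: normalized coords + unit normals.

    Horizontal coordinates are centered on the centroid; the vertical axis is
    referenced to the lowest point so absolute height along the plant is a
    usable cue for stem vs. main-stem.  Labels never enter the features; they
    are the supervision target only.
    """
    if cloud.normals is None:
        raise PointCloudError(
            "cloud has no normals; run estimate_normals_curvature first")
    coords = cloud.coords.copy()
    coords[:, :2] -= coords[:, :2].mean(axis=0)
    coords[:, 2] -= coords[:, 2].min()
    return np.column_stack([coords, cloud.normals])


def _rotate_features_z(features: np.ndarray, angle: float) -> np.ndarray:
    """Rotate the coordinate and normal channels about the vertical axis."""
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    out = features.copy()
    out[:, 0:2] = features[:, 0:2] @ rot.T
    out[:, 3:5] = features[:, 3:5] @ rot.T
    return out


def forward_segment(cloud: LabeledPointCloud, model: ResDGCNN) -> SegmentationResult:
    """Per-point organ logits and argmax classes for one sampled cloud."""
    feats = cloud_features(cloud)
    idx = knn_graph(cloud.coords, model.k)
    model.set_training(False)
    logits = model.forward(feats, idx).data
    return SegmentationResult(class_logits=logits, class_pred=logits.argmax(axis=1))


def segment_cloud(model: ResDGCNN, cloud: LabeledPointCloud, n_points: int = 2048,
                  rng_seed: int = 0) -> np.ndarray:
    """Predict a class for every point of an arbitrarily sized cloud.

    The cloud is sampled to the network's fixed size, normals are estimated
    on the sampled cloud (matching the training-time feature scale), the
    sample is segmented, and the predictions are propagated back to all
    points via the nearest sampled neighbor.
    """
    sampled = sample_fixed(cloud.replace(normals=None, curvature=None),
                           min(n_points, max(len(cloud) - 1, model.k + 1)),
                           rng_seed)
    sampled = estimate_normals_curvature(sampled, min(30, len(sampled) - 1))
    res = forward_segment(sampled, model)
    tree = cKDTree(sampled.coords)
    _, nearest = tree.query(cloud.coords, k=1)
    return res.class_pred[nearest]


def classify_period(cloud: LabeledPointCloud, clf: PeriodClassifier,
                    n_points: int = 256, rng_seed: int = 0) -> int:
    """Predict the growth period (1..4) of one cloud."""
    if cloud.normals is None:
        cloud = estimate_normals_curvature(cloud, min(30, max(3, len(cloud) // 2)))
    sampled = sample_fixed(cloud, n_points, rng_seed)
    feats = cloud_features(sampled)
    clf.set_training(False)
    logits = clf.forward(feats, np.zeros(len(feats), dtype=np.int64), 1).data
    return int(logits[0].argmax()) + 1


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _prepare_sample(cloud: LabeledPointCloud, n_points: int, k: int,
                    rng: np.random.Generator, normals_k: int = 30):
    """Drop background points, sample, estimate normals, build the graph."""
    if cloud.labels is not None:
        cloud = cloud.select(cloud.labels >= 0)
    sampled = sample_fixed(cloud, n_points, rng)
    # deduplicate for normal estimation robustness is unnecessary: kNN PCA
    # tolerates repeats as long as neighborhoods are not fully coincident
    sampled = estimate_normals_curvature(sampled, min(normals_k, len(sampled) - 1))
    return {
        "features": cloud_features(sampled),
        "labels": sampled.labels,
        "graph": knn_graph(sampled.coords, k),
        "period": cloud.period,
    }


def _batch(samples: list[dict]):
    feats = np.vstack([s["features"] for s in samples])
    labels = np.concatenate([s["labels"] for s in samples])
    seg_ids = np.concatenate([np.full(len(s["labels"]), i, dtype=np.int64)
                              for i, s in enumerate(samples)])
    offset = 0
    graphs = []
    for s in samples:
        graphs.append(s["graph"] + offset)
        offset += len(s["labels"])
    return feats, np.vstack(graphs), labels, seg_ids, len(samples)


def train(train_clouds: list[LabeledPointCloud],
          config: TrainConfig,
          test_clouds: list[LabeledPointCloud] | None = None,
          model: ResDGCNN | None = None,
          log_fn=None) -> tuple[ResDGCNN, dict]:
    """Cross-entropy training of the segmentation network.

    Returns the trained model and a loss trace with per-epoch mean train loss
    and (when a test set is given) test loss.  Deterministic given the
    config seed.
    """
    if not train_clouds:
        raise PointCloudError("empty training split")
    rng = np.random.default_rng(config.rng_seed)
    if model is None:
        model = ResDGCNN(in_channels=config.input_channels,
                         n_classes=config.n_classes, k=config.k,
                         rng_seed=int(rng.integers(0, 2**31 - 1)))
    samples = [_prepare_sample(c, config.n_points, config.k, rng)
               for c in train_clouds
               for _ in range(max(1, config.resamples_per_cloud))]
    test_samples = [_prepare_sample(c, config.n_points, config.k, rng)
                    for c in (test_clouds or [])]
    cw = None if config.class_weights is None else np.asarray(config.class_weights)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    trace = {"train_loss": [], "test_loss": []}
    order = np.arange(len(samples))
    for epoch in range(config.epochs):
        model.set_training(True)
        rng.shuffle(order)
        losses = []
        for start in range(0, len(order), config.batch_size):
            chunk = [samples[i] for i in order[start:start + config.batch_size]]
            feats, graph, labels, seg_ids, nseg = _batch(chunk)
            if config.rotation_augment:
                feats = _rotate_features_z(feats, rng.uniform(0.0, np.pi))
            logits = model.forward(feats, graph, seg_ids, nseg)
            loss = nn.cross_entropy(logits, labels, cw)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        trace["train_loss"].append(float(np.mean(losses)))
        if test_samples:
            model.set_training(False)
            feats, graph, labels, seg_ids, nseg = _batch(test_samples)
            logits = model.forward(feats, graph, seg_ids, nseg)
            trace["test_loss"].append(float(nn.cross_entropy(logits, labels, cw).data))
        if log_fn:
            log_fn(epoch, trace)
    model.set_training(False)
    return model, trace


def train_period_classifier(clouds: list[LabeledPointCloud],
                            periods: list[int], epochs: int = 150,
                            n_points: int = 256, learning_rate: float = 0.01,
                            rng_seed: int = 0) -> tuple[PeriodClassifier, list]:
    """Train the period classifier on labeled clouds; full-batch Adam."""
    if not clouds:
        raise PointCloudError("empty training split")
    rng = np.random.default_rng(rng_seed)
    clf = PeriodClassifier(rng_seed=int(rng.integers(0, 2**31 - 1)))
    feats, seg_ids = [], []
    for i, c in enumerate(clouds):
        if c.labels is not None:
            c = c.select(c.labels >= 0)
        if c.normals is None:
            c = estimate_normals_curvature(c, min(30, len(c) - 1))
        s = sample_fixed(c, n_points, rng)
        feats.append(cloud_features(s))
        seg_ids.append(np.full(n_points, i, dtype=np.int64))
    feats = np.vstack(feats)
    seg_ids = np.concatenate(seg_ids)
    target = np.asarray(periods, dtype=np.int64) - 1
    opt = nn.Adam(clf.parameters(), lr=learning_rate)
    losses = []
    for _ in range(epochs):
        logits = clf.forward(feats, seg_ids, len(clouds))
        loss = nn.cross_entropy(logits, target)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    clf.set_training(False)
    return clf, losses


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(model, path, extra_meta: dict | None = None) -> None:
    """Serialize a model to a single .npz checkpoint with a version header."""
    if isinstance(model, ResDGCNN):
        meta = {"kind": "resdgcnn", "in_channels": model.in_channels,
                "n_classes": model.n_classes, "k": model.k}
    elif isinstance(model, PeriodClassifier):
        meta = {"kind": "period", "in_channels": model.in_channels,
                "n_periods": model.n_periods}
    else:
        raise PointCloudError(f"cannot checkpoint {type(model).__name__}")
    meta["version"] = CHECKPOINT_VERSION
    meta.update(extra_meta or {})
    arrays = model.state_arrays()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path):
    """Load a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise PointCloudError(f"unsupported checkpoint version {meta.get('version')}")
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    if meta["kind"] == "resdgcnn":
        model = ResDGCNN(in_channels=meta["in_channels"],
                         n_classes=meta["n_classes"], k=meta["k"])
    else:
        model = PeriodClassifier(in_channels=meta["in_channels"],
                                 n_periods=meta["n_periods"])
    model.load_state_arrays(arrays)
    model.set_training(False)
    return model, meta
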