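"""Graph construction, edge convolution, residual blocks and training."""

import numpy as np
import pytest

from cottonphen import nn
from cottonphen import (PlantSpec, PointCloudError, TrainConfig,
                        classify_period, generate_plant, knn_graph,
                        load_checkpoint, save_checkpoint, train,
                        train_period_classifier)
from cottonphen.resdgcnn import (EdgeConv, EdgeConvSpec, PeriodClassifier,
                                 ResDGCNN, ResidualBlock, SegmentationResult,
                                 forward_segment, _prepare_sample, _batch)
from cottonphen.pointcloud_core import estimate_normals_curvature, sample_fixed


# ---------------------------------------------------------------------------
# knn graph
# ---------------------------------------------------------------------------

def brute_force_knn(coords, k):
    n = len(coords)
    out = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        d = np.linalg.norm(coords - coords[i], axis=1)
        d[i] = np.inf
        out[i] = np.argsort(d, kind="stable")[:k]
    return out


def test_knn_matches_brute_force_oracle(rng):
    for _ in range(10):
        n = int(rng.integers(30, 200))
        coords = rng.normal(size=(n, 3))
        k = int(rng.integers(1, 8))
        assert np.array_equal(knn_graph(coords, k), brute_force_knn(coords, k))


def test_knn_tie_breaks_to_lower_index():
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
    idx = knn_graph(coords, 1)
    assert idx[1, 0] == 0          # middle point: both endpoints at distance 1


def test_knn_full_graph_is_permutation(rng):
    coords = rng.normal(size=(12, 3))
    idx = knn_graph(coords, 11)
    for i in range(12):
        assert sorted(idx[i]) == [j for j in range(12) if j != i]


def test_knn_rejects_small_clouds(rng):
    with pytest.raises(PointCloudError):
        knn_graph(rng.normal(size=(5, 3)), 5)


def test_knn_large_cloud_consistent_with_small_path(rng):
    coords = rng.normal(size=(3000, 3))     # kd-tree branch
    idx = knn_graph(coords, 4)
    sub = rng.integers(0, 3000, 20)
    for i in sub:
        d = np.linalg.norm(coords - coords[i], axis=1)
        d[i] = np.inf
        assert set(idx[i]) == set(np.argsort(d)[:4])


# ---------------------------------------------------------------------------
# edge convolution
# ---------------------------------------------------------------------------

def leaky(v, s=0.2):
    return np.where(v > 0, v, s * v)


def test_edge_conv_matches_hand_computation(rng):
    layer = EdgeConv(EdgeConvSpec(2, 2, k=1), rng)
    theta = np.array([[1.0, -0.5], [0.3, 2.0]])
    theta_p = np.array([[0.7, 0.1], [-1.0, 0.4]])
    layer.theta.weight.data = theta
    layer.theta.bias.data = np.zeros(2)
    layer.theta_prime.weight.data = theta_p
    layer.theta_prime.bias.data = np.zeros(2)
    x = np.array([[1.0, 2.0], [-1.0, 0.5]])
    idx = np.array([[1], [0]])
    out = layer(nn.Tensor(x), idx).data
    # e_ij = LeakyReLU((x_i - x_j) @ theta) + LeakyReLU(x_j @ theta')
    for i, j in ((0, 1), (1, 0)):
        e = leaky((x[i] - x[j]) @ theta) + leaky(x[j] @ theta_p)
        assert np.allclose(out[i], e)


def test_edge_conv_identical_points_give_identical_outputs(rng):
    layer = EdgeConv(EdgeConvSpec(3, 4, k=2), rng)
    x = np.tile([[0.5, -1.0, 2.0]], (5, 1))
    idx = np.array([[1, 2], [0, 2], [0, 1], [4, 0], [3, 0]])
    out = layer(nn.Tensor(x), idx).data
    assert np.allclose(out, out[0])


def test_edge_conv_permutation_equivariant(rng):
    layer = EdgeConv(EdgeConvSpec(3, 5, k=3), rng)
    x = rng.normal(size=(10, 3))
    idx = knn_graph(x, 3)
    out = layer(nn.Tensor(x), idx).data
    perm = rng.permutation(10)
    inv = np.argsort(perm)
    out_p = layer(nn.Tensor(x[perm]), inv[idx[perm]]).data
    assert np.allclose(out_p, out[perm])


# ---------------------------------------------------------------------------
# residual block
# ---------------------------------------------------------------------------

def _inference_identity_block(rng, c=2):
    blk = ResidualBlock(c, c, rng)
    for conv in (blk.conv_a, blk.conv_b):
        conv.weight.data = np.eye(c)
        conv.bias.data = np.zeros(c)
    for bn in (blk.bn_a, blk.bn_b):
        bn.running_mean = np.zeros(c)
        bn.running_var = np.ones(c) - bn.eps    # unit stats after eps
        bn.training = False
    return blk


def test_residual_block_hand_arithmetic(rng):
    blk = _inference_identity_block(rng)
    x = np.array([[3.0, -2.0]])
    out = blk(nn.Tensor(x)).data
    expected = leaky(leaky(x) + x)      # pathA = LReLU(BN(x)), pathB = BN(x)
    assert np.allclose(out, expected)


def test_residual_block_preserves_zero(rng):
    blk = _inference_identity_block(rng, c=3)
    out = blk(nn.Tensor(np.zeros((4, 3)))).data
    assert np.allclose(out, 0.0)


def test_gradient_flows_through_skip_path(rng):
    blk = ResidualBlock(3, 3, rng)
    blk.conv_a.weight.data[:] = 0.0     # kill path A's conv
    x = nn.Tensor(rng.normal(size=(6, 3)), requires_grad=True)
    blk(x).sum().backward()
    assert np.any(np.abs(x.grad) > 1e-8)


def test_residual_block_channel_mismatch_rejected(rng):
    blk = ResidualBlock(3, 4, rng)
    with pytest.raises(ValueError):
        blk(nn.Tensor(np.zeros((2, 5))))


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_sampled_cloud():
    cloud, _ = generate_plant(PlantSpec(period=1, n_leaves=3, rng_seed=4))
    sampled = sample_fixed(cloud.select(cloud.labels >= 0), 128, 0)
    return estimate_normals_curvature(sampled, 20)


def test_forward_shapes_and_finiteness(small_sampled_cloud):
    model = ResDGCNN(rng_seed=0)
    res = forward_segment(small_sampled_cloud, model)
    assert res.class_logits.shape == (128, 5)
    assert np.all(np.isfinite(res.class_logits))
    assert res.class_pred.shape == (128,)


def test_network_permutation_equivariant(small_sampled_cloud, rng):
    model = ResDGCNN(rng_seed=0)
    res = forward_segment(small_sampled_cloud, model)
    perm = rng.permutation(len(small_sampled_cloud))
    res_p = forward_segment(small_sampled_cloud.select(perm), model)
    assert np.allclose(res_p.class_logits, res.class_logits[perm], atol=1e-9)


def test_duplicated_point_gets_identical_logits(small_sampled_cloud):
    model = ResDGCNN(rng_seed=0)
    dup = small_sampled_cloud.select(
        np.r_[np.arange(len(small_sampled_cloud)), 0])
    res = forward_segment(dup, model)
    assert np.allclose(res.class_logits[-1], res.class_logits[0], atol=1e-9)


def test_segmentation_result_argmax_consistency():
    logits = np.array([[0.0, 1.0], [2.0, -1.0]])
    with pytest.raises(PointCloudError):
        SegmentationResult(class_logits=logits, class_pred=np.array([0, 0]))


def test_missing_normals_give_actionable_error():
    cloud, _ = generate_plant(PlantSpec(period=1, n_leaves=2, rng_seed=0))
    model = ResDGCNN(rng_seed=0)
    with pytest.raises(PointCloudError, match="estimate_normals_curvature"):
        forward_segment(cloud, model)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_training_set():
    clouds = []
    for seed in range(4):
        spec = PlantSpec(period=1, n_leaves=4, mainstem_height=0.25,
                         rng_seed=seed)
        c, _ = generate_plant(spec)
        clouds.append(c)
    return clouds


def test_training_loss_descends(tiny_training_set):
    cfg = TrainConfig(epochs=8, n_points=256, rng_seed=1,
                      resamples_per_cloud=1, rotation_augment=False)
    _, trace = train(tiny_training_set, cfg)
    assert trace["train_loss"][-1] < trace["train_loss"][0]


def test_training_is_deterministic(tiny_training_set):
    cfg = TrainConfig(epochs=3, n_points=256, rng_seed=1,
                      resamples_per_cloud=1)
    _, t1 = train(tiny_training_set, cfg)
    _, t2 = train(tiny_training_set, cfg)
    assert np.allclose(t1["train_loss"], t2["train_loss"], atol=1e-6)


def test_empty_split_rejected():
    with pytest.raises(PointCloudError):
        train([], TrainConfig(epochs=1))


def test_checkpoint_round_trip(tiny_training_set, tmp_path, small_sampled_cloud):
    cfg = TrainConfig(epochs=2, n_points=256, rng_seed=1, resamples_per_cloud=1)
    model, _ = train(tiny_training_set, cfg)
    path = tmp_path / "model.npz"
    save_checkpoint(model, path, {"note": "test"})
    loaded, meta = load_checkpoint(path)
    assert meta["note"] == "test"
    a = forward_segment(small_sampled_cloud, model).class_logits
    b = forward_segment(small_sampled_cloud, loaded).class_logits
    assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# period classifier
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def period_dataset():
    rng = np.random.default_rng(21)
    clouds, periods = [], []
    for period in (1, 2, 3, 4):
        for _ in range(8):
            spec = PlantSpec.for_period(period, rng, overlap_fraction=0.2,
                                        outlier_count=0)
            c, _ = generate_plant(spec)
            clouds.append(c)
            periods.append(period)
    return clouds, periods


def test_period_classifier_learns_periods(period_dataset):
    clouds, periods = period_dataset
    train_idx = [i for i in range(len(clouds)) if i % 4 != 3]
    test_idx = [i for i in range(len(clouds)) if i % 4 == 3]
    clf, losses = train_period_classifier(
        [clouds[i] for i in train_idx], [periods[i] for i in train_idx],
        epochs=200, rng_seed=0)
    assert losses[-1] < losses[0]
    correct = sum(classify_period(clouds[i], clf) == periods[i]
                  for i in test_idx)
    assert correct / len(test_idx) >= 0.75


def test_period_prediction_permutation_invariant(period_dataset, rng):
    clouds, periods = period_dataset
    clf, _ = train_period_classifier(clouds[:4], periods[:4], epochs=30,
                                     rng_seed=0)
    # fix the sampled point set so permutation only reorders the multiset
    cloud = clouds[0].select(clouds[0].labels >= 0)
    sampled = estimate_normals_curvature(sample_fixed(cloud, 256, 0), 20)
    perm = rng.permutation(256)
    assert (classify_period(sampled, clf, n_points=256)
            == classify_period(sampled.select(perm), clf, n_points=256))


def test_single_period_training_predicts_that_period(period_dataset):
    clouds, periods = period_dataset
    p2 = [c for c, p in zip(clouds, periods) if p == 2]
    clf, _ = train_period_classifier(p2, [2] * len(p2), epochs=60, rng_seed=0)
    assert all(classify_period(c, clf) == 2 for c in p2[:3])
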