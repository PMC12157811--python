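import numpy as np
import pytest

from cottonphen import (LabeledPointCloud, PlantSpec, estimate_normals_curvature,
                        generate_plant)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plane_cloud(rng):
    """500 points on the z=0 plane over a 10 cm square."""
    xy = rng.uniform(-0.05, 0.05, (500, 2))
    return LabeledPointCloud(np.column_stack([xy, np.zeros(500)]))


@pytest.fixture(scope="session")
def twelve_leaf_plant():
    """Bud-stage plant with 12 leaves, half of them in overlapping pairs."""
    spec = PlantSpec(period=2, n_leaves=12, n_buds=4, mainstem_height=0.45,
                     overlap_fraction=0.5, rng_seed=1)
    return generate_plant(spec)


@pytest.fixture(scope="session")
def twelve_leaf_geometry(twelve_leaf_plant):
    """Leaf-class points of the 12-leaf plant with normals and curvature."""
    cloud, truth = twelve_leaf_plant
    leaf = cloud.select(cloud.labels == 0)
    return estimate_normals_curvature(leaf, 16), truth


def best_match_agreement(true_inst, pred_inst):
    """Pointwise agreement under the best one-to-one instance matching."""
    from scipy.optimize import linear_sum_assignment
    mask = pred_inst >= 0
    tids = np.unique(true_inst)
    pids = np.unique(pred_inst[mask]) if mask.any() else np.array([], dtype=int)
    if len(pids) == 0:
        return 0.0
    overlap = np.zeros((len(tids), len(pids)))
    for i, t in enumerate(tids):
        for j, p in enumerate(pids):
            overlap[i, j] = np.sum((true_inst == t) & (pred_inst == p))
    r, c = linear_sum_assignment(-overlap)
    return overlap[r, c].sum() / len(true_inst)
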