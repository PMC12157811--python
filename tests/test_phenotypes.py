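"""Plant height, stem length, pot-plane alignment and shedding rate."""

import numpy as np
import pytest

from cottonphen import (LabeledPointCloud, PlantSpec, PointCloudError,
                        SheddingRecord, align_to_pot_plane, generate_plant,
                        plant_height, shedding_from_clouds, shedding_rate,
                        stem_length)
from cottonphen.pointcloud_core import add_jitter, rotate_z


# ---------------------------------------------------------------------------
# shedding rate
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("I,E,expected_int", [
    (1, 1, 0), (3, 2, 33), (7, 3, 57), (4, 3, 25), (3, 1, 66),
])
def test_shedding_rate_integer_truncation(I, E, expected_int):
    rec = shedding_rate(I, E)
    assert rec.rate_int == expected_int
    assert rec.rate_exact == pytest.approx(100.0 * (I - E) / I)


def test_shedding_rate_contract_errors():
    with pytest.raises(PointCloudError):
        shedding_rate(0, 0)
    with pytest.raises(PointCloudError):
        shedding_rate(3, 4)
    with pytest.raises(PointCloudError):
        SheddingRecord(I=2, E=-1)


def test_shedding_rate_bounds_and_monotonicity():
    for I in (1, 4, 9):
        rates = [shedding_rate(I, E).rate_exact for E in range(I + 1)]
        assert all(0.0 <= r <= 100.0 for r in rates)
        assert rates == sorted(rates, reverse=True)   # decreasing in E


# ---------------------------------------------------------------------------
# plant height
# ---------------------------------------------------------------------------

def test_height_of_two_points():
    cloud = LabeledPointCloud(np.array([[0, 0, 0], [0, 0, 0.42]], float))
    assert plant_height(cloud) == pytest.approx(0.42)


def test_height_single_point_is_zero():
    assert plant_height(LabeledPointCloud(np.array([[1.0, 2, 3]]))) == 0.0


def test_height_empty_cloud_rejected():
    with pytest.raises(PointCloudError):
        plant_height(LabeledPointCloud(np.empty((0, 3))))


def test_height_excludes_background_points():
    coords = np.array([[0, 0, 0], [0, 0, 0.5], [0, 0, 9.0]])
    labels = np.array([2, 0, -1])     # the 9 m point is an outlier
    assert plant_height(LabeledPointCloud(coords, labels=labels)) == 0.5


def test_height_invariant_under_z_rotation_and_translation(rng):
    cloud = LabeledPointCloud(rng.normal(size=(300, 3)))
    h = plant_height(cloud)
    assert plant_height(rotate_z(cloud, 1.1)) == h
    shifted = cloud.replace(coords=cloud.coords + np.array([5.0, -2.0, 0.0]))
    assert plant_height(shifted) == h


def test_height_tracks_truth_under_bounded_jitter(rng):
    amplitude = 0.01
    for seed in (1, 2):
        cloud, truth = generate_plant(PlantSpec(period=2, n_leaves=10,
                                                n_buds=3, rng_seed=seed))
        noisy = add_jitter(cloud, amplitude, rng)
        assert abs(plant_height(noisy) - truth.height_true) <= 2 * amplitude


# ---------------------------------------------------------------------------
# stem length
# ---------------------------------------------------------------------------

def test_stem_length_collinear_points_exact():
    pts = np.column_stack([np.linspace(0, 1.0, 11), np.zeros(11), np.zeros(11)])
    assert stem_length(LabeledPointCloud(pts)) == pytest.approx(1.0)


def test_stem_length_helix_matches_closed_form():
    r, c = 0.05, 0.10                     # z = c * phi
    phi = np.linspace(0, 4 * np.pi, 4000)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), c * phi])
    exact = np.sqrt(r**2 + c**2) * (4 * np.pi)
    est = stem_length(LabeledPointCloud(pts))
    assert abs(est - exact) / exact < 0.02


def test_stem_length_on_synthetic_mainstem():
    for seed in (3, 4, 5):
        cloud, truth = generate_plant(PlantSpec(period=2, n_leaves=8,
                                                n_buds=2, rng_seed=seed))
        ms = cloud.select(cloud.labels == 2)
        est = stem_length(ms)
        assert abs(est - truth.stem_length_true) / truth.stem_length_true <= 0.05


def test_stem_length_rigid_motion_invariant(rng):
    pts = np.column_stack([np.zeros(200), np.zeros(200),
                           np.sort(rng.uniform(0, 0.5, 200))])
    pts[:, 0] = 0.02 * np.sin(pts[:, 2] * 20)
    cloud = LabeledPointCloud(pts)
    base = stem_length(cloud)
    rotated = rotate_z(cloud, 0.9)
    assert stem_length(rotated) == pytest.approx(base, abs=1e-9)
    shifted = cloud.replace(coords=cloud.coords + [1.0, 2.0, 3.0])
    assert stem_length(shifted) == pytest.approx(base, abs=1e-9)


def test_stem_length_exceeds_endpoint_distance(rng):
    pts = np.column_stack([0.05 * np.sin(np.linspace(0, 6, 300)),
                           np.zeros(300), np.linspace(0, 0.6, 300)])
    cloud = LabeledPointCloud(pts)
    ends = np.linalg.norm(pts[-1] - pts[0])
    assert stem_length(cloud) >= ends - 1e-12


def test_stem_length_needs_two_points():
    with pytest.raises(PointCloudError):
        stem_length(LabeledPointCloud(np.array([[0.0, 0, 0]])))


# ---------------------------------------------------------------------------
# pot-plane alignment
# ---------------------------------------------------------------------------

def tilted(cloud, angle_deg):
    a = np.deg2rad(angle_deg)
    rot = np.array([[1, 0, 0],
                    [0, np.cos(a), -np.sin(a)],
                    [0, np.sin(a), np.cos(a)]])
    return cloud.replace(coords=cloud.coords @ rot.T)


@pytest.fixture
def potted_plant():
    cloud, truth = generate_plant(PlantSpec(period=2, n_leaves=8, n_buds=2,
                                            include_pot=True, rng_seed=8))
    return cloud, truth


def test_alignment_of_aligned_cloud_is_identity(potted_plant):
    cloud, _ = potted_plant
    out = align_to_pot_plane(cloud)
    # residual tilt from stem-base points in the lowest decile stays
    # below a fraction of a degree (sub-millimeter displacement)
    assert np.max(np.abs(out.coords - cloud.coords)) < 2e-3


def test_tilt_and_realign_recovers_height(potted_plant):
    cloud, truth = potted_plant
    realigned = align_to_pot_plane(tilted(cloud, 25))
    baseline = align_to_pot_plane(cloud)
    # the 25-degree tilt is removed exactly: both paths land on the same
    # alignment, and the height matches the generating truth closely
    assert abs(plant_height(realigned) - plant_height(baseline)) < 1e-6
    assert abs(plant_height(realigned) - truth.height_true) < 1e-4


def test_alignment_preserves_pairwise_distances(potted_plant):
    cloud, _ = potted_plant
    out = align_to_pot_plane(tilted(cloud, 15))
    idx = np.arange(0, len(cloud), 97)
    d0 = np.linalg.norm(cloud.coords[idx, None] - cloud.coords[None, idx], axis=2)
    d1 = np.linalg.norm(out.coords[idx, None] - out.coords[None, idx], axis=2)
    assert np.max(np.abs(d0 - d1)) < 1e-9


def test_collinear_base_rejected():
    line = np.column_stack([np.linspace(0, 0.1, 200), np.zeros(200),
                            np.zeros(200)])
    top = np.tile([[0.05, 0.0, 0.5]], (20, 1))
    cloud = LabeledPointCloud(np.vstack([line, top]))
    with pytest.raises(PointCloudError, match="collinear|consensus"):
        align_to_pot_plane(cloud)


# ---------------------------------------------------------------------------
# shedding from segmented clouds
# ---------------------------------------------------------------------------

def test_shedding_from_synthetic_cloud_pair():
    bud_stage, _ = generate_plant(PlantSpec(period=2, n_leaves=10, n_buds=7,
                                            mainstem_height=0.5, rng_seed=13))
    final, _ = generate_plant(PlantSpec(period=4, n_leaves=10, n_buds=0,
                                        n_bolls=3, mainstem_height=0.6,
                                        rng_seed=14))
    rec = shedding_from_clouds(bud_stage, final)
    assert (rec.I, rec.E) == (7, 3)
    assert rec.rate_int == 57


def test_identical_boll_clouds_shed_nothing():
    cloud, _ = generate_plant(PlantSpec(period=4, n_leaves=8, n_buds=0,
                                        n_bolls=3, rng_seed=15))
    rec = shedding_from_clouds(cloud, cloud)
    assert rec.E == rec.I == 3 and rec.rate_exact == 0.0


def test_zero_final_bolls_is_total_shedding():
    bud_stage, _ = generate_plant(PlantSpec(period=2, n_leaves=6, n_buds=4,
                                            rng_seed=16))
    final, _ = generate_plant(PlantSpec(period=1, n_leaves=6, rng_seed=17))
    rec = shedding_from_clouds(bud_stage, final)
    assert rec.I == 4 and rec.E == 0 and rec.rate_int == 100
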