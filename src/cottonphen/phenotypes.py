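"""Phenotype extraction: plant height, main-stem path length, shedding rate.

Plant height is H = Zmax - Zmin over the plant points after the pot plane
has been aligned horizontal.  Main-stem length is the accumulated Euclidean
distance along an ordered skeleton of the main-stem points: the points are
binned along their principal (near-vertical) axis, bin centroids form a
polyline, and segment lengths are summed — robust to scatter across the stem
girth.  The shedding (bell-drop) rate compares the peak bud count I with the
count E surviving to boll maturity: rate = (I - E)/I x 100%, reported both
exactly and as an integer percent truncated toward zero (the convention of
per-plant shedding tables, where 66.67 prints as 66%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pointcloud_core import (BOLL, BUD, LabeledPointCloud, PointCloudError,
                              estimate_normals_curvature)
from .region_growing import RegionGrowingParams, count_instances, grow_regions


@dataclass(frozen=True)
class SheddingRecord:
    """Bud census I, surviving count E, and the derived shedding rate."""

    I: int
    E: int

    def __post_init__(self):
        if self.I < 1:
            raise PointCloudError("shedding rate undefined for I = 0")
        if not 0 <= self.E <= self.I:
            raise PointCloudError("need 0 <= E <= I")

    @property
    def rate_exact(self) -> float:
        return 100.0 * (self.I - self.E) / self.I

    @property
    def rate_int(self) -> int:
        """Integer percent, truncated toward zero (66.67 -> 66)."""
        return math.trunc(self.rate_exact)


@dataclass
class PhenotypeRecord:
    """Per-plant phenotypes: height H (m), stem length Lstem (m), shedding."""

    H: float
    Lstem: float
    shedding: SheddingRecord | None = None

    def __post_init__(self):
        if self.H < 0 or self.Lstem < 0:
            raise PointCloudError("phenotypes must be non-negative")


def shedding_rate(I: int, E: int) -> SheddingRecord:
    """Shedding rate from the total bud count I and surviving count E."""
    return SheddingRecord(I=int(I), E=int(E))


# ---------------------------------------------------------------------------
# pot-plane alignment
# ---------------------------------------------------------------------------

def _fit_plane_ransac(points: np.ndarray, inlier_threshold: float = 0.005,
                      n_trials: int = 200, rng_seed: int = 0):
    """Consensus plane (centroid, unit normal) on the given points."""
    rng = np.random.default_rng(rng_seed)
    n = len(points)
    if n < 3:
        raise PointCloudError("need at least 3 base points to fit the pot plane")
    best_inliers = None
    for _ in range(n_trials):
        idx = rng.choice(n, 3, replace=False)
        a, b, c = points[idx]
        normal = np.cross(b - a, c - a)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            continue
        normal /= norm
        d = np.abs((points - a) @ normal)
        inliers = d < inlier_threshold
        if best_inliers is None or inliers.sum() > best_inliers.sum():
            best_inliers = inliers
    if best_inliers is None or best_inliers.sum() < 3:
        raise PointCloudError("degenerate pot base: no plane consensus")

    def refit(pts):
        centroid = pts.mean(axis=0)
        _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
        if s[1] < 1e-9 * max(s[0], 1e-30):
            raise PointCloudError("degenerate pot base: points are collinear")
        normal = vt[2]
        return centroid, (normal if normal[2] >= 0 else -normal)

    centroid, normal = refit(points[best_inliers])
    # one refinement pass at half the threshold sheds off-plane stragglers
    # (e.g. stem-base points caught by the coarse consensus band)
    tight = np.abs((points - centroid) @ normal) < inlier_threshold / 2.0
    if tight.sum() >= 3:
        try:
            centroid, normal = refit(points[tight])
        except PointCloudError:
            pass
    return centroid, normal


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(a @ b)
    if c < -1 + 1e-12:          # antiparallel: rotate pi about any orthogonal
        axis = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        axis = axis - (axis @ a) * a
        axis /= np.linalg.norm(axis)
        return 2 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def align_to_pot_plane(cloud: LabeledPointCloud, base_fraction: float = 0.1,
                       inlier_threshold: float = 0.005) -> LabeledPointCloud:
    """Rotate the cloud so the pot plane is horizontal (normal along +z).

    A consensus plane is fitted to the lowest ``base_fraction`` of points by
    height; the rigid rotation about the plane centroid maps its normal to
    the z-axis.  Distances are preserved; the fit is deterministically
    seeded.
    """
    if len(cloud) < 3:
        raise PointCloudError("cannot align a cloud with fewer than 3 points")
    z = cloud.coords[:, 2]
    cut = np.quantile(z, base_fraction)
    base = cloud.coords[z <= cut]
    centroid, normal = _fit_plane_ransac(base, inlier_threshold)
    rot = _rotation_between(normal, np.array([0.0, 0.0, 1.0]))
    coords = (cloud.coords - centroid) @ rot.T + centroid
    normals = None if cloud.normals is None else cloud.normals @ rot.T
    return cloud.replace(coords=coords, normals=normals)


# ---------------------------------------------------------------------------
# height and stem length
# ---------------------------------------------------------------------------

def plant_height(cloud: LabeledPointCloud) -> float:
    """H = Zmax - Zmin over the plant points of an aligned cloud.

    When labels are present, background/pot points (label -1) are excluded
    so the pot rim does not bias the minimum.
    """
    if len(cloud) == 0:
        raise PointCloudError("cannot measure an empty cloud")
    pts = cloud.coords
    if cloud.labels is not None and (cloud.labels >= 0).any():
        pts = pts[cloud.labels >= 0]
    return float(pts[:, 2].max() - pts[:, 2].min())


def stem_length(mainstem_cloud: LabeledPointCloud, bin_size: float = 0.01) -> float:
    """Main-stem path length by Euclidean-distance accumulation.

    The main-stem points are projected onto their principal axis (oriented
    upward), binned at ``bin_size`` (default 1 cm), and the polyline through
    the bin centroids is accumulated — this orders the skeleton and avoids
    double-counting the stem girth.
    """
    coords = mainstem_cloud.coords
    if len(coords) < 2:
        raise PointCloudError("need at least 2 main-stem points")
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid, full_matrices=False)
    axis = vt[0]
    if abs(axis[2]) > 1e-9:
        axis = axis if axis[2] > 0 else -axis
    elif axis[np.abs(axis).argmax()] < 0:
        axis = -axis
    t = (coords - centroid) @ axis
    bins = np.floor((t - t.min()) / bin_size + 1e-9).astype(np.int64)
    order = np.unique(bins)
    if len(order) < 2:
        raise PointCloudError("fewer than 2 skeleton points after binning")
    centroids = np.stack([coords[bins == b].mean(axis=0) for b in order])
    return float(np.linalg.norm(np.diff(centroids, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# shedding from segmented clouds
# ---------------------------------------------------------------------------

#: region-growing settings for compact blob organs (buds, bolls): the gates
#: are loosened — an ellipsoid has no smooth interior to grow over — and the
#: spatial separation between organs does the work through kNN adjacency.
BLOB_PARAMS = RegionGrowingParams(theta=np.pi / 2, k_curv=0.9,
                                  min_region_points=15, adjacency_k=8)


def _instances_of_classes(cloud: LabeledPointCloud, classes: tuple,
                          params: RegionGrowingParams) -> int:
    if cloud.labels is None:
        raise PointCloudError("shedding_from_clouds needs semantic labels")
    sub = cloud.select(np.isin(cloud.labels, classes))
    if len(sub) == 0:
        return 0
    # geometry is re-estimated on the class subset so neighborhoods never
    # straddle points of other organs
    sub = sub.replace(normals=None, curvature=None)
    sub = estimate_normals_curvature(sub, min(16, max(3, len(sub) - 1)))
    return count_instances(grow_regions(sub, params))


def shedding_from_clouds(bud_stage_cloud: LabeledPointCloud,
                         final_stage_cloud: LabeledPointCloud,
                         params: RegionGrowingParams | None = None) -> SheddingRecord:
    """Shedding rate from two segmented clouds of the same plant.

    I is the instance count of bud+boll points at the bud-stage acquisition
    (the plant's peak bud census); E is the boll instance count at the final
    (fluffing-stage) acquisition.
    """
    if params is None:
        params = BLOB_PARAMS
    I = _instances_of_classes(bud_stage_cloud, (BUD, BOLL), params)
    if I == 0:
        raise PointCloudError("no buds found at the bud stage; rate undefined")
    E = _instances_of_classes(final_stage_cloud, (BOLL,), params)
    E = min(E, I)    # census cannot grow after the peak
    return SheddingRecord(I=I, E=E)
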