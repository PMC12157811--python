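"""Parametric generator of labeled single-plant cotton point clouds.

Real full-growth-period cotton scans are rarely shareable, so this module
produces structurally comparable stand-ins with exact ground truth: a gently
curved main stem (class 2), petioles/branches (class 1), curved overlapping
leaf blades (class 0), buds (class 3) and bolls (class 4) across the four
growth periods, plus background outliers (label -1).  Every cloud carries
per-point organ labels and instance ids, and the generating geometry yields
the true plant height, main-stem path length and organ counts, enabling
parameter-recovery tests of the whole pipeline.

Growth periods follow the organ-count staging of the field: period 1
(emergence/seedling) has leaves, stems and the main stem only; period 2 (bud
stage) adds buds; periods 3-4 (boll stages) add bolls.  Leaf counts per
period emulate the reported ranges (a handful of leaves in period 1, 20-30
around the bud stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pointcloud_core import (BACKGROUND, BOLL, BUD, LEAF, MAINSTEM, STEM,
                              LabeledPointCloud, PointCloudError,
                              write_point_cloud)


@dataclass
class PlantSpec:
    """Parameters of one synthetic plant; all lengths in meters."""

    period: int = 1
    n_leaves: int = 6
    n_buds: int = 0
    n_bolls: int = 0
    mainstem_height: float = 0.3
    mainstem_waviness: float = 0.03   # lateral wander as fraction of height
    leaf_radius_range: tuple = (0.015, 0.03)
    overlap_fraction: float = 0.0     # fraction of leaves placed in close pairs
    overlap_gap: float = 0.005        # vertical clearance inside an overlapping pair
    outlier_count: int = 0
    include_pot: bool = False         # planar pot disc under the stem base (label -1)
    leaf_density: float = 3.0e5       # points per m^2 of blade area
    rng_seed: int = 0

    def __post_init__(self):
        if self.period not in (1, 2, 3, 4):
            raise PointCloudError(f"period must be 1..4, got {self.period}")
        if self.period == 1 and (self.n_buds or self.n_bolls):
            raise PointCloudError("period 1 allows classes {leaf, stem, mainstem} only")
        if self.period == 2 and self.n_bolls:
            raise PointCloudError("bolls appear only in periods 3-4")
        if self.n_leaves < 1:
            raise PointCloudError("need at least one leaf")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise PointCloudError("overlap_fraction must be in [0, 1]")

    @staticmethod
    def for_period(period: int, rng: np.random.Generator,
                   overlap_fraction: float = 0.3, outlier_count: int = 40,
                   include_pot: bool = False) -> "PlantSpec":
        """Draw a period-typical spec (leaf counts per the staging ranges)."""
        if period == 1:
            n_leaves, n_buds, n_bolls = int(rng.integers(3, 9)), 0, 0
            height = rng.uniform(0.15, 0.30)
        elif period == 2:
            n_leaves, n_buds, n_bolls = int(rng.integers(20, 31)), int(rng.integers(3, 9)), 0
            height = rng.uniform(0.35, 0.55)
        elif period == 3:
            n_leaves, n_buds = int(rng.integers(20, 31)), int(rng.integers(3, 8))
            n_bolls = int(rng.integers(1, 4))
            height = rng.uniform(0.50, 0.70)
        else:
            n_leaves, n_buds = int(rng.integers(15, 26)), int(rng.integers(0, 3))
            n_bolls = int(rng.integers(3, 7))
            height = rng.uniform(0.60, 0.80)
        return PlantSpec(period=period, n_leaves=n_leaves, n_buds=n_buds,
                         n_bolls=n_bolls, mainstem_height=height,
                         overlap_fraction=overlap_fraction,
                         outlier_count=outlier_count, include_pot=include_pot,
                         rng_seed=int(rng.integers(0, 2**31 - 1)))


@dataclass
class GroundTruth:
    """Exact per-point and per-plant truth for one generated plant."""

    labels: np.ndarray
    instance_ids: np.ndarray
    height_true: float
    stem_length_true: float
    n_leaves_true: int
    n_buds_true: int
    n_bolls_true: int
    phenotypes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane orthogonal to ``axis``."""
    axis = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(axis, u)


def _tube_points(polyline: np.ndarray, radius: float, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Random points on the surface of a tube swept along a polyline."""
    seg = np.diff(polyline, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    t = rng.uniform(0.0, cum[-1], n)
    k = np.clip(np.searchsorted(cum, t, side="right") - 1, 0, len(seg) - 1)
    frac = (t - cum[k]) / seg_len[k]
    centers = polyline[k] + frac[:, None] * seg[k]
    phi = rng.uniform(0.0, 2 * np.pi, n)
    pts = np.empty((n, 3))
    for i in range(n):
        u, v = _orthonormal_frame(seg[k[i]])
        pts[i] = centers[i] + radius * (np.cos(phi[i]) * u + np.sin(phi[i]) * v)
    return pts


def _leaf_patch(center: np.ndarray, normal: np.ndarray, a: float, b: float,
                n: int, rng: np.random.Generator, bend: float = 0.15,
                p: float = 2.5) -> np.ndarray:
    """Superellipse blade in the tangent plane with parabolic bending.

    ``bend`` sets the sag as a fraction of the semi-major axis; with the
    default the surface normal deviates at most ~17 degrees from the blade
    normal, so region growing with a 30-degree gate keeps a blade whole.
    """
    u, v = _orthonormal_frame(normal)
    pts = np.empty((n, 3))
    got = 0
    while got < n:
        m = 2 * (n - got)
        uu = rng.uniform(-a, a, m)
        vv = rng.uniform(-b, b, m)
        keep = (np.abs(uu / a) ** p + np.abs(vv / b) ** p) <= 1.0
        uu, vv = uu[keep][: n - got], vv[keep][: n - got]
        w = bend * (uu**2 + vv**2) / a
        pts[got: got + len(uu)] = (center + uu[:, None] * u + vv[:, None] * v
                                   + w[:, None] * (normal / np.linalg.norm(normal)))
        got += len(uu)
    return pts


def _ellipsoid_points(center: np.ndarray, semi_axes: np.ndarray, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return center + d * semi_axes


# ---------------------------------------------------------------------------
# plant assembly
# ---------------------------------------------------------------------------

def _mainstem_polyline(spec: PlantSpec, rng: np.random.Generator,
                       n_segments: int = 200) -> np.ndarray:
    """Gently curved vertical polyline from the soil line to the stem apex."""
    z = np.linspace(0.0, spec.mainstem_height, n_segments + 1)
    amp = spec.mainstem_waviness * spec.mainstem_height
    phase_x, phase_y = rng.uniform(0, 2 * np.pi, 2)
    freq = rng.uniform(1.0, 1.8)
    x = amp * np.sin(freq * np.pi * z / spec.mainstem_height + phase_x)
    y = amp * np.sin(freq * np.pi * z / spec.mainstem_height + phase_y)
    return np.column_stack([x, y, z])


def _polyline_length(poly: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())


def _point_on_polyline(poly: np.ndarray, frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Point and tangent at arc-length fraction ``frac`` of the polyline."""
    seg = np.diff(poly, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = frac * cum[-1]
    k = int(np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1))
    t = (s - cum[k]) / seg_len[k]
    return poly[k] + t * seg[k], seg[k] / seg_len[k]


def generate_plant(spec: PlantSpec) -> tuple[LabeledPointCloud, GroundTruth]:
    """Generate one labeled plant cloud with exact ground truth.

    Deterministic given ``spec.rng_seed``.  The returned cloud has integer
    ``labels`` (organ classes, -1 for outliers/pot) and an ``instance``
    column in ``extra`` (-1 for outliers/pot); the ground truth records the
    exact plant height (z-extent of the organ points), the arc length of the
    generating main-stem polyline, and the organ counts.
    """
    rng = np.random.default_rng(spec.rng_seed)
    chunks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    instances: list[np.ndarray] = []
    next_instance = 0

    def add(points: np.ndarray, cls: int, instance: int):
        chunks.append(points)
        labels.append(np.full(len(points), cls, dtype=np.int64))
        instances.append(np.full(len(points), instance, dtype=np.int64))

    # main stem (one instance of class 2)
    poly = _mainstem_polyline(spec, rng)
    stem_length_true = _polyline_length(poly)
    n_ms = max(250, int(900 * spec.mainstem_height))
    add(_tube_points(poly, radius=0.004, n=n_ms, rng=rng), MAINSTEM, next_instance)
    next_instance += 1

    # leaf placement: heights/azimuths along the stem; a chosen fraction of
    # leaves is placed in close vertical pairs to create the overlapping-leaf
    # regime that instance segmentation must disentangle.
    n_pairs = int(round(spec.overlap_fraction * spec.n_leaves / 2.0))
    golden = np.deg2rad(137.5)
    leaf_slots: list[tuple[float, float, int | None]] = []   # (height_frac, azimuth, partner)
    i = 0
    slot = 0
    while len(leaf_slots) < spec.n_leaves:
        hf = 0.18 + 0.75 * (slot + rng.uniform(-0.2, 0.2)) / max(spec.n_leaves - n_pairs, 1)
        hf = float(np.clip(hf, 0.12, 0.97))
        az = (slot * golden + rng.uniform(-0.2, 0.2)) % (2 * np.pi)
        leaf_slots.append((hf, az, None))
        if i < n_pairs and len(leaf_slots) < spec.n_leaves:
            leaf_slots.append((hf, az, len(leaf_slots) - 1))   # overlapping partner
            i += 1
        slot += 1

    a_lo, a_hi = spec.leaf_radius_range
    bend = 0.12
    leaf_info: list[tuple[np.ndarray, float, np.ndarray]] = []   # (center, a, normal)
    for j, (hf, az, partner) in enumerate(leaf_slots):
        base, _tangent = _point_on_polyline(poly, hf)
        a = rng.uniform(a_lo, a_hi)
        if partner is None:
            out_dir = np.array([np.cos(az), np.sin(az), 0.0])
            tilt = rng.uniform(0.35, 0.75)      # petiole elevation angle, rad
            pet_dir = np.cos(tilt) * out_dir + np.sin(tilt) * np.array([0.0, 0.0, 1.0])
            tip = base + rng.uniform(0.04, 0.08) * pet_dir
            lean = rng.uniform(0.2, 0.55)       # blade normal tilt from vertical
            az_n = az + rng.uniform(-0.5, 0.5)
            normal = np.array([np.sin(lean) * np.cos(az_n),
                               np.sin(lean) * np.sin(az_n), np.cos(lean)])
            center = tip + 0.6 * a * (pet_dir - pet_dir @ normal * normal)
        else:
            # overlapping partner: a blade stacked over its partner along the
            # partner's normal, tilted so the two normals differ well beyond
            # the region-growing gate; the stand-off keeps the closest
            # approach of the two surfaces near the stated overlap gap.
            p_center, p_a, p_normal = leaf_info[partner]
            u_ax, _ = _orthonormal_frame(p_normal)
            delta = rng.choice([-1.0, 1.0]) * rng.uniform(0.6, 0.8)
            c, s = np.cos(delta), np.sin(delta)
            # Rodrigues rotation of p_normal about the in-plane axis u_ax
            normal = (c * p_normal + s * np.cross(u_ax, p_normal))
            normal /= np.linalg.norm(normal)
            standoff = spec.overlap_gap + a * abs(s) + bend * a
            center = (p_center + standoff * p_normal
                      + rng.uniform(-0.2, 0.2) * p_a * u_ax)
            tip = center - 0.5 * a * _orthonormal_frame(normal)[0]
        pet_vec = tip - base
        pet_len = float(np.linalg.norm(pet_vec))
        pet_poly = np.vstack([base, tip])
        n_pet = max(40, int(1500 * pet_len))
        add(_tube_points(pet_poly, radius=0.0015, n=n_pet, rng=rng), STEM, next_instance)
        next_instance += 1
        b = 0.7 * a
        n_leaf = max(150, int(spec.leaf_density * 3.7 * a * b))
        add(_leaf_patch(center, normal, a, b, n_leaf, rng, bend=bend), LEAF, next_instance)
        leaf_info.append((center, a, normal))
        next_instance += 1

    # buds and bolls on short stalks off the upper stem; rejection sampling
    # keeps distinct blobs from interpenetrating (organs touch but do not
    # occupy the same space)
    placed: list[tuple[np.ndarray, float]] = []
    for cls, count, semi in ((BUD, spec.n_buds, np.array([0.004, 0.004, 0.007])),
                             (BOLL, spec.n_bolls, np.array([0.012, 0.012, 0.016]))):
        r_max = float(semi.max())
        for _ in range(count):
            center = None
            for _attempt in range(60):
                hf = rng.uniform(0.45, 0.95)
                base, _ = _point_on_polyline(poly, hf)
                az = rng.uniform(0, 2 * np.pi)
                stalk = np.array([np.cos(az), np.sin(az), 0.6])
                stalk /= np.linalg.norm(stalk)
                cand = base + rng.uniform(0.015, 0.035) * stalk
                if all(np.linalg.norm(cand - c) >= r + r_max + 0.005
                       for c, r in placed):
                    center = cand
                    break
            if center is None:          # crowded stem: accept the last draw
                center = cand
            placed.append((center, r_max))
            n_pts = 60 if cls == BUD else 160
            add(_ellipsoid_points(center, semi, n_pts, rng), cls, next_instance)
            next_instance += 1

    organ_points = np.vstack(chunks)
    height_true = float(organ_points[:, 2].max() - organ_points[:, 2].min())

    if spec.include_pot:
        r = np.sqrt(rng.uniform(0, 1, 400)) * 0.06
        phi = rng.uniform(0, 2 * np.pi, 400)
        pot = np.column_stack([r * np.cos(phi), r * np.sin(phi),
                               rng.uniform(-0.002, 0.0, 400) - 0.003])
        add(pot, BACKGROUND, -1)

    if spec.outlier_count:
        lo = organ_points.min(axis=0) - 0.1
        hi = organ_points.max(axis=0) + 0.1
        add(rng.uniform(lo, hi, (spec.outlier_count, 3)), BACKGROUND, -1)

    cloud = LabeledPointCloud(
        coords=np.vstack(chunks),
        labels=np.concatenate(labels),
        period=spec.period,
        extra={"instance": np.concatenate(instances)},
    )
    truth = GroundTruth(
        labels=cloud.labels.copy(),
        instance_ids=cloud.extra["instance"].copy(),
        height_true=height_true,
        stem_length_true=stem_length_true,
        n_leaves_true=spec.n_leaves,
        n_buds_true=spec.n_buds,
        n_bolls_true=spec.n_bolls,
        phenotypes={"height_m": height_true, "stem_length_m": stem_length_true},
    )
    return cloud, truth


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

DEFAULT_PERIOD_MIX = {1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}


def generate_dataset(n_plants: int, period_mix: dict | None = None,
                     out_dir=None, rng_seed: int = 0,
                     overlap_fraction: float = 0.3, outlier_count: int = 40,
                     include_pot: bool = False) -> pd.DataFrame:
    """Generate ``n_plants`` plants, write PLY files and a manifest table.

    The train:test split is 4:1, stratified by period.  Returns the manifest
    as a DataFrame; when ``out_dir`` is given, PLY files and
    ``manifest.csv`` are written there.
    """
    if n_plants < 5:
        raise PointCloudError("need at least 5 plants for a 4:1 split")
    mix = period_mix or DEFAULT_PERIOD_MIX
    total = sum(mix.values())
    # largest-remainder apportionment of plants to periods
    quotas = {p: n_plants * w / total for p, w in mix.items() if w > 0}
    counts = {p: int(np.floor(q)) for p, q in quotas.items()}
    remainder = n_plants - sum(counts.values())
    for p in sorted(quotas, key=lambda p: quotas[p] - counts[p], reverse=True)[:remainder]:
        counts[p] += 1

    rng = np.random.default_rng(rng_seed)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
    rows = []
    plant_idx = 0
    for period in sorted(counts):
        n_p = counts[period]
        n_test = int(round(n_p / 5.0))
        for j in range(n_p):
            spec = PlantSpec.for_period(period, rng, overlap_fraction=overlap_fraction,
                                        outlier_count=outlier_count,
                                        include_pot=include_pot)
            cloud, truth = generate_plant(spec)
            fname = f"plant_{plant_idx:04d}.ply"
            if out_dir is not None:
                write_point_cloud(cloud, Path(out_dir) / fname,
                                  comments=[f"seed={spec.rng_seed}"])
            rows.append({
                "file": fname, "period": period,
                "split": "test" if j >= n_p - n_test else "train",
                "n_points": len(cloud),
                "height_true_m": truth.height_true,
                "stem_length_true_m": truth.stem_length_true,
                "n_leaves": spec.n_leaves, "n_buds": spec.n_buds,
                "n_bolls": spec.n_bolls, "seed": spec.rng_seed,
            })
            plant_idx += 1
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return manifest
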