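"""Point-cloud domain types, file I/O, depth filtering and augmentation.

The universal currency of the pipeline is :class:`LabeledPointCloud`: per-point
coordinates in meters, optional unit normals, optional surface-variation
curvature, optional organ labels (0=leaf, 1=stem, 2=mainstem, 3=bud, 4=boll,
-1=background/outlier) and an optional growth-period tag (1..4).

Supported file dialects are PLY (ascii and binary_little_endian), ascii PCD,
and plain whitespace tables with 3 (xyz), 6 (xyz + normal) or 7 (+ label)
columns.  Extra integer per-point columns such as predicted class (``pred``)
or instance id (``instance``) travel in ``cloud.extra``.
"""

from __future__ import annotations

import dataclasses
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: organ class codes used throughout the pipeline
LEAF, STEM, MAINSTEM, BUD, BOLL = 0, 1, 2, 3, 4
BACKGROUND = -1
ORGAN_CLASSES = (LEAF, STEM, MAINSTEM, BUD, BOLL)
CLASS_NAMES = {LEAF: "leaf", STEM: "stem", MAINSTEM: "mainstem",
               BUD: "bud", BOLL: "boll", BACKGROUND: "background"}

_VALID_LABELS = frozenset((-1, 0, 1, 2, 3, 4))


class PointCloudError(ValueError):
    """Raised for malformed files or contract violations."""


@dataclass
class LabeledPointCloud:
    """N points with coordinates (meters) and optional per-point attributes."""

    coords: np.ndarray
    normals: np.ndarray | None = None
    curvature: np.ndarray | None = None
    labels: np.ndarray | None = None
    period: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise PointCloudError("coordinates must be finite")
        n = len(self.coords)
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64).reshape(-1, 3)
            if len(self.normals) != n:
                raise PointCloudError("normals length mismatch")
            norms = np.linalg.norm(self.normals, axis=1)
            if n and not np.allclose(norms, 1.0, atol=1e-5):
                raise PointCloudError("normals must be unit vectors")
        if self.curvature is not None:
            self.curvature = np.asarray(self.curvature, dtype=np.float64).ravel()
            if len(self.curvature) != n:
                raise PointCloudError("curvature length mismatch")
            if n and (self.curvature.min() < -1e-12 or self.curvature.max() > 1.0 + 1e-12):
                raise PointCloudError("curvature must lie in [0, 1]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.dtype.kind == "f" and not np.all(self.labels == np.round(self.labels)):
                raise PointCloudError("labels must be integers")
            self.labels = self.labels.astype(np.int64).ravel()
            if len(self.labels) != n:
                raise PointCloudError("labels length mismatch")
            bad = set(np.unique(self.labels)) - _VALID_LABELS
            if bad:
                raise PointCloudError(f"labels outside the five-class scheme: {sorted(bad)}")
        if self.period is not None and self.period not in (1, 2, 3, 4):
            raise PointCloudError(f"period must be in 1..4, got {self.period}")
        for k, v in self.extra.items():
            self.extra[k] = np.asarray(v).ravel()
            if len(self.extra[k]) != n:
                raise PointCloudError(f"extra column {k!r} length mismatch")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_points(self) -> int:
        return len(self.coords)

    def select(self, index) -> "LabeledPointCloud":
        """Subset by boolean mask or integer index, all attributes in lockstep."""
        return LabeledPointCloud(
            coords=self.coords[index],
            normals=None if self.normals is None else self.normals[index],
            curvature=None if self.curvature is None else self.curvature[index],
            labels=None if self.labels is None else self.labels[index],
            period=self.period,
            extra={k: v[index] for k, v in self.extra.items()},
        )

    def replace(self, **kw) -> "LabeledPointCloud":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class DepthFilterBounds:
    """Axis-aligned closed box [xmin,xmax]x[ymin,ymax]x[zmin,zmax], meters."""

    xmin: float = -np.inf
    xmax: float = np.inf
    ymin: float = -np.inf
    ymax: float = np.inf
    zmin: float = -np.inf
    zmax: float = np.inf

    def __post_init__(self):
        for lo, hi, ax in ((self.xmin, self.xmax, "x"), (self.ymin, self.ymax, "y"),
                           (self.zmin, self.zmax, "z")):
            if lo > hi:
                raise PointCloudError(f"{ax}: min > max in depth-filter bounds")

    @property
    def lows(self) -> np.ndarray:
        return np.array([self.xmin, self.ymin, self.zmin])

    @property
    def highs(self) -> np.ndarray:
        return np.array([self.xmax, self.ymax, self.zmax])


@dataclass(frozen=True)
class AugmentationConfig:
    """Amplitude ranges for the three training-set augmentations."""

    gaussian_amplitude_range: tuple = (0.02, 0.05)  # m, per-cloud sigma
    rotation_range_deg: tuple = (0.0, 180.0)
    jitter_amplitude_range: tuple = (0.0, 0.05)     # m, uniform per point
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("gaussian_amplitude_range", "rotation_range_deg",
                     "jitter_amplitude_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise PointCloudError(f"{name} must be non-negative and ordered")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_PLY_FLOAT = {"float": ("<f4", 4), "float32": ("<f4", 4),
              "double": ("<f8", 8), "float64": ("<f8", 8)}
_PLY_INT = {"char": ("<i1", 1), "int8": ("<i1", 1), "uchar": ("<u1", 1),
            "uint8": ("<u1", 1), "short": ("<i2", 2), "int16": ("<i2", 2),
            "ushort": ("<u2", 2), "uint16": ("<u2", 2), "int": ("<i4", 4),
            "int32": ("<i4", 4), "uint": ("<u4", 4), "uint32": ("<u4", 4)}
_NORMAL_ALIASES = {"nx": "nx", "ny": "ny", "nz": "nz",
                   "normal_x": "nx", "normal_y": "ny", "normal_z": "nz"}


def _columns_to_cloud(names: list[str], cols: dict, path, period=None) -> LabeledPointCloud:
    for ax in ("x", "y", "z"):
        if ax not in cols:
            raise PointCloudError(f"{path}: missing coordinate property {ax!r}")
    coords = np.column_stack([cols["x"], cols["y"], cols["z"]])
    normals = None
    if all(a in cols for a in ("nx", "ny", "nz")):
        normals = np.column_stack([cols["nx"], cols["ny"], cols["nz"]])
    curvature = cols.get("curvature")
    labels = cols.get("label")
    known = {"x", "y", "z", "nx", "ny", "nz", "curvature", "label"}
    extra = {k: np.asarray(v, dtype=np.int64) for k, v in cols.items() if k not in known}
    try:
        return LabeledPointCloud(coords, normals=normals, curvature=curvature,
                                 labels=labels, period=period, extra=extra)
    except PointCloudError as exc:
        raise PointCloudError(f"{path}: {exc}") from exc


def _read_ply(path: Path) -> LabeledPointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise PointCloudError(f"{path}: not a PLY file")
        fmt = None
        props: list[tuple[str, str]] = []   # (name, type) for element vertex
        n_vertex = None
        in_vertex = False
        period = None
        while True:
            line = fh.readline()
            if not line:
                raise PointCloudError(f"{path}: unexpected end of header")
            tok = line.decode("ascii", "replace").split()
            if not tok:
                continue
            if tok[0] == "format":
                fmt = tok[1]
            elif tok[0] == "comment":
                if len(tok) >= 2 and tok[1].startswith("period="):
                    period = int(tok[1].split("=", 1)[1])
            elif tok[0] == "element":
                in_vertex = tok[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tok[2])
            elif tok[0] == "property" and in_vertex:
                if tok[1] == "list":
                    raise PointCloudError(f"{path}: list properties unsupported on vertex")
                props.append((tok[2], tok[1]))
            elif tok[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise PointCloudError(f"{path}: unsupported PLY format {fmt!r}")
        if n_vertex is None:
            raise PointCloudError(f"{path}: no vertex element")
        names = [_NORMAL_ALIASES.get(n, n) for n, _ in props]
        if fmt == "ascii":
            rows = []
            for i in range(n_vertex):
                line = fh.readline()
                vals = line.split()
                if len(vals) != len(props):
                    raise PointCloudError(
                        f"{path}: vertex record {i} has {len(vals)} values, expected {len(props)}")
                rows.append([float(v) for v in vals])
            arr = np.asarray(rows, dtype=np.float64).reshape(n_vertex, len(props))
            cols = {}
            for j, (name, (_, typ)) in enumerate(zip(names, props)):
                c = arr[:, j]
                cols[name] = c.astype(np.int64) if typ in _PLY_INT else c
        else:
            dtype = np.dtype([(f"f{j}", (_PLY_FLOAT.get(t) or _PLY_INT.get(t) or
                                         _err_type(path, t))[0])
                              for j, (_, t) in enumerate(props)])
            buf = fh.read(dtype.itemsize * n_vertex)
            if len(buf) != dtype.itemsize * n_vertex:
                raise PointCloudError(f"{path}: truncated binary vertex data")
            rec = np.frombuffer(buf, dtype=dtype)
            cols = {}
            for j, (name, (_, typ)) in enumerate(zip(names, props)):
                c = rec[f"f{j}"]
                cols[name] = c.astype(np.int64) if typ in _PLY_INT else c.astype(np.float64)
        return _columns_to_cloud(names, cols, path, period=period)


def _err_type(path, t):
    raise PointCloudError(f"{path}: unsupported PLY property type {t!r}")


def _read_pcd(path: Path) -> LabeledPointCloud:
    fields = sizes = types = None
    n_points = None
    data_mode = None
    with open(path, "r") as fh:
        for line in fh:
            tok = line.split()
            if not tok or tok[0] == "#":
                continue
            key = tok[0].upper()
            if key == "FIELDS":
                fields = tok[1:]
            elif key == "SIZE":
                sizes = tok[1:]
            elif key == "TYPE":
                types = tok[1:]
            elif key == "POINTS":
                n_points = int(tok[1])
            elif key == "DATA":
                data_mode = tok[1]
                break
        if data_mode != "ascii":
            raise PointCloudError(f"{path}: only ascii PCD is supported")
        if fields is None or n_points is None:
            raise PointCloudError(f"{path}: malformed PCD header")
        rows = []
        for i, line in enumerate(fh):
            vals = line.split()
            if not vals:
                continue
            if len(vals) != len(fields):
                raise PointCloudError(f"{path}: point record {i} has wrong arity")
            rows.append([float(v) for v in vals])
    if len(rows) != n_points:
        raise PointCloudError(f"{path}: POINTS={n_points} but {len(rows)} records found")
    arr = np.asarray(rows, dtype=np.float64).reshape(n_points, len(fields))
    names = [_NORMAL_ALIASES.get(f, f) for f in fields]
    cols = {}
    for j, (name, typ) in enumerate(zip(names, types or ["F"] * len(names))):
        c = arr[:, j]
        cols[name] = c.astype(np.int64) if typ.upper() in ("I", "U") else c
    return _columns_to_cloud(names, cols, path)


def _read_ascii_table(path: Path) -> LabeledPointCloud:
    rows = []
    width = None
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            vals = s.split()
            if width is None:
                width = len(vals)
                if width not in (3, 6, 7):
                    raise PointCloudError(
                        f"{path}:{lineno}: expected 3, 6 or 7 columns, found {width}")
            elif len(vals) != width:
                raise PointCloudError(
                    f"{path}:{lineno}: inconsistent column count "
                    f"({len(vals)} vs {width})")
            try:
                rows.append([float(v) for v in vals])
            except ValueError as exc:
                raise PointCloudError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise PointCloudError(f"{path}: empty point table")
    arr = np.asarray(rows, dtype=np.float64)
    names = ["x", "y", "z"]
    if width >= 6:
        names += ["nx", "ny", "nz"]
    if width == 7:
        names += ["label"]
    cols = {n: arr[:, j] for j, n in enumerate(names)}
    if "label" in cols:
        cols["label"] = cols["label"].astype(np.int64)
    return _columns_to_cloud(names, cols, path)


def read_point_cloud(path, format_hint: str | None = None) -> LabeledPointCloud:
    """Read a PLY / PCD / whitespace-table point cloud.

    Missing attributes are left absent on the returned cloud, never fabricated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "pcd":
        return _read_pcd(path)
    return _read_ascii_table(path)


def write_point_cloud(cloud: LabeledPointCloud, path, format: str | None = None,
                      binary: bool = False, comments: list[str] | None = None) -> None:
    """Write a cloud losslessly (coords/normals/labels) as PLY, PCD or table.

    Floats are stored as 64-bit (PLY ``double``, 17-significant-digit ascii)
    so a write/read round trip is bit exact.
    """
    if len(cloud) == 0:
        raise PointCloudError("refusing to write an empty point cloud")
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("ply", "pcd", "xyz", "txt", "asc"):
        raise PointCloudError(f"unsupported output format {fmt!r}")

    names: list[tuple[str, str, np.ndarray]] = [
        ("x", "double", cloud.coords[:, 0]),
        ("y", "double", cloud.coords[:, 1]),
        ("z", "double", cloud.coords[:, 2]),
    ]
    if cloud.normals is not None:
        for j, n in enumerate(("nx", "ny", "nz")):
            names.append((n, "double", cloud.normals[:, j]))
    if cloud.curvature is not None:
        names.append(("curvature", "double", cloud.curvature))
    if cloud.labels is not None:
        names.append(("label", "int", cloud.labels))
    for k, v in cloud.extra.items():
        names.append((k, "int", v))

    if fmt == "ply":
        header = ["ply",
                  "format binary_little_endian 1.0" if binary else "format ascii 1.0"]
        if cloud.period is not None:
            header.append(f"comment period={cloud.period}")
        for c in comments or []:
            header.append(f"comment {c}")
        header.append(f"element vertex {len(cloud)}")
        header += [f"property {t} {n}" for n, t, _ in names]
        header.append("end_header")
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            if binary:
                rec = np.empty(len(cloud), dtype=np.dtype(
                    [(n, "<f8" if t == "double" else "<i4") for n, t, _ in names]))
                for n, t, col in names:
                    rec[n] = col
                fh.write(rec.tobytes())
            else:
                for i in range(len(cloud)):
                    fh.write((" ".join(
                        f"{col[i]:.17g}" if t == "double" else str(int(col[i]))
                        for _, t, col in names) + "\n").encode("ascii"))
        return

    if fmt == "pcd":
        pcd_fields = [n for n, _, _ in names]
        with open(path, "w") as fh:
            fh.write("# .PCD v0.7 - Point Cloud Data file format\n")
            fh.write("VERSION 0.7\n")
            fh.write("FIELDS " + " ".join(pcd_fields) + "\n")
            fh.write("SIZE " + " ".join("8" if t == "double" else "4" for _, t, _ in names) + "\n")
            fh.write("TYPE " + " ".join("F" if t == "double" else "I" for _, t, _ in names) + "\n")
            fh.write("COUNT " + " ".join("1" for _ in names) + "\n")
            fh.write(f"WIDTH {len(cloud)}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\n")
            fh.write(f"POINTS {len(cloud)}\nDATA ascii\n")
            for i in range(len(cloud)):
                fh.write(" ".join(
                    f"{col[i]:.17g}" if t == "double" else str(int(col[i]))
                    for _, t, col in names) + "\n")
        return

    # plain whitespace table: x y z [nx ny nz] [label]
    with open(path, "w") as fh:
        for i in range(len(cloud)):
            row = [f"{v:.17g}" for v in cloud.coords[i]]
            if cloud.normals is not None:
                row += [f"{v:.17g}" for v in cloud.normals[i]]
            if cloud.labels is not None:
                row.append(str(int(cloud.labels[i])))
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# depth filtering
# ---------------------------------------------------------------------------

def depth_filter(cloud: LabeledPointCloud, bounds: DepthFilterBounds) -> LabeledPointCloud:
    """Keep exactly the points whose x, y and z lie inside the closed box.

    Generalizes single-axis depth thresholding to an axis-aligned crop that
    strips background/outlier structure around the plant; attribute rows are
    filtered in lockstep.  Idempotent; an empty result is legal.
    """
    mask = np.all((cloud.coords >= bounds.lows) & (cloud.coords <= bounds.highs), axis=1)
    return cloud.select(mask)


# ---------------------------------------------------------------------------
# normals and curvature
# ---------------------------------------------------------------------------

def estimate_normals_curvature(cloud: LabeledPointCloud,
                               neighborhood_size: int = 30) -> LabeledPointCloud:
    """PCA normals and surface-variation curvature from k-neighborhoods.

    For each point the covariance of its ``neighborhood_size`` nearest
    neighbors (self included) is eigen-decomposed; the normal is the
    eigenvector of the smallest eigenvalue and the curvature is the surface
    variation lambda0/(lambda0+lambda1+lambda2), bounded in [0, 1/3].
    Normals are unoriented; the sign is fixed deterministically so repeated
    runs agree.  Degenerate (coincident) neighborhoods get curvature 0 and an
    arbitrary unit normal, with a warning.
    """
    n = len(cloud)
    if n < neighborhood_size:
        raise PointCloudError(
            f"need at least neighborhood_size={neighborhood_size} points, have {n}")
    tree = cKDTree(cloud.coords)
    _, idx = tree.query(cloud.coords, k=neighborhood_size)
    nbrs = cloud.coords[idx]                       # (n, k, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / neighborhood_size
    evals, evecs = np.linalg.eigh(cov)             # ascending eigenvalues
    total = evals.sum(axis=1)
    degenerate = total <= 1e-300
    if degenerate.any():
        logger.warning("degenerate neighborhoods for %d points; "
                       "curvature set to 0, arbitrary unit normal", degenerate.sum())
    curvature = np.zeros(n)
    ok = ~degenerate
    curvature[ok] = np.maximum(evals[ok, 0], 0.0) / total[ok]
    normals = evecs[:, :, 0].copy()
    normals[degenerate] = (0.0, 0.0, 1.0)
    # deterministic sign: largest-|component| made positive
    lead = np.abs(normals).argmax(axis=1)
    sign = np.sign(normals[np.arange(n), lead])
    sign[sign == 0] = 1.0
    normals *= sign[:, None]
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return cloud.replace(normals=normals, curvature=np.clip(curvature, 0.0, 1.0))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_fixed(cloud: LabeledPointCloud, n_points: int,
                 rng_seed: int | np.random.Generator = 0) -> LabeledPointCloud:
    """Uniform random sample to exactly ``n_points`` points.

    Without replacement when the cloud is at least that large, with
    replacement otherwise (keeps the fixed-size contract the network needs).
    Deterministic given the seed.
    """
    if len(cloud) == 0:
        raise PointCloudError("cannot sample an empty cloud")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    replace = len(cloud) < n_points
    idx = rng.choice(len(cloud), size=n_points, replace=replace)
    return cloud.select(idx)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def rotate_z(cloud: LabeledPointCloud, angle_rad: float) -> LabeledPointCloud:
    """Rigid rotation about the vertical axis through the cloud centroid.

    Normals are co-rotated; labels and curvature are unchanged.
    """
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    centroid = cloud.coords.mean(axis=0)
    coords = (cloud.coords - centroid) @ rot.T + centroid
    normals = None if cloud.normals is None else cloud.normals @ rot.T
    return cloud.replace(coords=coords, normals=normals)


def add_gaussian(cloud: LabeledPointCloud, sigma: float,
                 rng: np.random.Generator) -> LabeledPointCloud:
    """Zero-mean Gaussian displacement, i.i.d. per point and axis."""
    return cloud.replace(coords=cloud.coords + rng.normal(0.0, sigma, cloud.coords.shape))


def add_jitter(cloud: LabeledPointCloud, amplitude: float,
               rng: np.random.Generator) -> LabeledPointCloud:
    """Per-point uniform perturbation bounded by ``amplitude`` per coordinate."""
    return cloud.replace(coords=cloud.coords +
                         rng.uniform(-amplitude, amplitude, cloud.coords.shape))


def augment(cloud: LabeledPointCloud, config: AugmentationConfig,
            which: str, rng: np.random.Generator | None = None) -> LabeledPointCloud:
    """Apply one of the three training augmentations.

    ``gaussian`` draws one sigma per cloud from the configured range and adds
    i.i.d. Gaussian displacement; ``rotation`` rotates rigidly about the
    vertical axis through the centroid by an angle uniform in the configured
    range; ``jitter`` adds bounded per-point uniform perturbation.  Only
    coordinates are perturbed by the noise augmentations; rotation co-rotates
    the normals.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if which == "gaussian":
        lo, hi = config.gaussian_amplitude_range
        return add_gaussian(cloud, rng.uniform(lo, hi), rng)
    if which == "rotation":
        lo, hi = np.deg2rad(config.rotation_range_deg)
        return rotate_z(cloud, rng.uniform(lo, hi))
    if which == "jitter":
        lo, hi = config.jitter_amplitude_range
        return add_jitter(cloud, rng.uniform(lo, hi), rng)
    raise PointCloudError(f"unknown augmentation {which!r}")
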