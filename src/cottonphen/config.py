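"""Pipeline configuration: defaults, YAML loading, validation, provenance."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .pointcloud_core import PointCloudError

#: every tunable of the pipeline with its default
DEFAULTS = {
    "io": {"format": "ply"},
    "filter": {"xmin": None, "xmax": None, "ymin": None, "ymax": None,
               "zmin": None, "zmax": None},
    "normals": {"k": 30},
    "sample": {"n": 2048},
    "augment": {"seed": 0,
                "gaussian_amplitude_range": [0.02, 0.05],
                "rotation_range_deg": [0.0, 180.0],
                "jitter_amplitude_range": [0.0, 0.05]},
    "train": {"weight_decay": 0.01, "learning_rate": 0.001, "epochs": 200,
              "batch_size": 2, "n_points": 2048, "k": 20, "n_classes": 5},
    "region_growing": {"theta_deg": 30.0, "k_curv": 0.05, "max_regions": 64,
                       "min_region_points": 30, "merge_enabled": True,
                       "adjacency_k": 10},
    "phenotype": {"stem_bin_m": 0.01, "base_fraction": 0.1},
    "pipeline": {"rng_seed": 0, "log_level": "INFO"},
}


class PipelineConfig:
    """Validated nested key/value configuration with YAML round trip."""

    def __init__(self, values: dict | None = None):
        self.values = copy.deepcopy(DEFAULTS)
        if values:
            self._merge(self.values, values, path="")

    @staticmethod
    def _merge(base: dict, override: dict, path: str):
        for key, val in override.items():
            here = f"{path}{key}"
            if key not in base:
                raise PointCloudError(f"unknown config key {here!r}")
            if isinstance(base[key], dict):
                if not isinstance(val, dict):
                    raise PointCloudError(f"config key {here!r} expects a mapping")
                PipelineConfig._merge(base[key], val, here + ".")
            else:
                base[key] = val

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise PointCloudError("config file must hold a mapping")
        return cls(raw)

    def __getitem__(self, dotted: str):
        node = self.values
        for part in dotted.split("."):
            node = node[part]
        return node

    def set(self, dotted: str, value):
        parts = dotted.split(".")
        node = self.values
        for part in parts[:-1]:
            node = node[part]
        if parts[-1] not in node:
            raise PointCloudError(f"unknown config key {dotted!r}")
        node[parts[-1]] = value

    def digest(self) -> str:
        """Short stable hash of the configuration for output provenance."""
        blob = json.dumps(self.values, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def region_growing_params(self):
        from .region_growing import RegionGrowingParams
        rg = self.values["region_growing"]
        return RegionGrowingParams(
            theta=float(np.deg2rad(rg["theta_deg"])), k_curv=float(rg["k_curv"]),
            max_regions=int(rg["max_regions"]),
            min_region_points=int(rg["min_region_points"]),
            merge_enabled=bool(rg["merge_enabled"]),
            adjacency_k=int(rg["adjacency_k"]))

    def depth_filter_bounds(self):
        from .pointcloud_core import DepthFilterBounds
        f = self.values["filter"]
        inf = float("inf")
        return DepthFilterBounds(
            xmin=f["xmin"] if f["xmin"] is not None else -inf,
            xmax=f["xmax"] if f["xmax"] is not None else inf,
            ymin=f["ymin"] if f["ymin"] is not None else -inf,
            ymax=f["ymax"] if f["ymax"] is not None else inf,
            zmin=f["zmin"] if f["zmin"] is not None else -inf,
            zmax=f["zmax"] if f["zmax"] is not None else inf)
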