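"""File formats: NIfTI-1 volumes, YAML configuration, provenance records.

Volumes are written as NIfTI-1 with an axis-aligned affine (voxel sizes on
the diagonal, origin in the translation column).  Companion volumes must
share dims, voxel size and origin; mismatches raise an alignment error
naming both files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .cohort import (
    ClinicalConfig, CohortConfig, EffectsConfig, Gaussian, GeometryConfig,
    GroupDemographics, SbrModel, ScoreModel,
)
from .grid import VoxelGrid, grids_compatible


class AlignmentError(ValueError):
    pass


def write_volume(path, data: np.ndarray, grid: VoxelGrid) -> None:
    img = nib.Nifti1Image(np.asarray(data), grid.affine)
    img.header.set_zooms(tuple(grid.voxel_size) + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-4):
        raise ValueError(f"{path}: only axis-aligned volumes are supported")
    voxel = tuple(float(v) for v in np.diag(aff[:3, :3]))
    grid = VoxelGrid(dims=data.shape[:3], voxel_size=voxel,
                     origin=tuple(float(v) for v in aff[:3, 3]))
    return data, grid


def read_aligned(*paths) -> tuple[list[np.ndarray], VoxelGrid]:
    """Read companion volumes, enforcing a shared grid."""
    arrays: list[np.ndarray] = []
    grid0: VoxelGrid | None = None
    first = None
    for p in paths:
        data, grid = read_volume(p)
        if grid0 is None:
            grid0, first = grid, p
        elif not grids_compatible(grid0, grid):
            raise AlignmentError(
                f"grid mismatch between {first} ({grid0.dims}, {grid0.voxel_size}) "
                f"and {p} ({grid.dims}, {grid.voxel_size})"
            )
        arrays.append(data)
    assert grid0 is not None
    return arrays, grid0


# ---------------------------------------------------------------------------
# configuration serialisation
# ---------------------------------------------------------------------------

def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def cohort_config_to_yaml(config: CohortConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_plain(config), sort_keys=True))


def _gaussian(v):
    if v is None:
        return None
    if isinstance(v, dict):
        return Gaussian(**v)
    return Gaussian(*v)


def cohort_config_from_dict(d: dict) -> CohortConfig:
    demo = {
        g: GroupDemographics(
            age=_gaussian(v["age"]), male_fraction=v["male_fraction"],
            moca=_gaussian(v["moca"]), tiv_cm3=_gaussian(v["tiv_cm3"]),
            tsmv_cm3=_gaussian(v["tsmv_cm3"]),
            duration_years=_gaussian(v.get("duration_years")),
        )
        for g, v in d.get("demographics", {}).items()
    } or None
    sbr = d.get("sbr_model")
    if sbr is not None:
        sbr = SbrModel(group={g: _gaussian(v) for g, v in sbr["group"].items()},
                       **{k: v for k, v in sbr.items() if k != "group"})
    geo = d.get("geometry")
    if geo is not None:
        geo = dict(geo)
        for key in ("grid_dims", "hemisphere_aspect"):
            if key in geo:
                geo[key] = tuple(geo[key])
        geo = GeometryConfig(**geo)
    kwargs = dict(
        n_control=d.get("n_control", 45), n_irbd=d.get("n_irbd", 56),
        n_pd=d.get("n_pd", 72), seed=d.get("seed", 0),
    )
    if demo:
        kwargs["demographics"] = demo
    if sbr:
        kwargs["sbr_model"] = sbr
    if geo:
        kwargs["geometry"] = geo
    if "score_model" in d:
        kwargs["score_model"] = ScoreModel(**d["score_model"])
    if "effects" in d:
        kwargs["effects"] = EffectsConfig(**d["effects"])
    if "clinical" in d:
        kwargs["clinical"] = ClinicalConfig(**d["clinical"])
    return CohortConfig(**kwargs)


def cohort_config_from_yaml(path) -> CohortConfig:
    return cohort_config_from_dict(yaml.safe_load(Path(path).read_text()) or {})


def config_hash(config) -> str:
    """Platform-stable hash of a configuration dataclass."""
    blob = json.dumps(_plain(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ProvenanceRecord:
    tool_version: str
    config_hash: str
    seed: int
    counts: dict[str, int]
    timestamp: str

    @classmethod
    def create(cls, config, seed: int, counts: dict[str, int]) -> "ProvenanceRecord":
        return cls(tool_version=__version__, config_hash=config_hash(config),
                   seed=seed, counts=dict(counts),
                   timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))
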