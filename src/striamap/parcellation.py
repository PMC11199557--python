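"""Connectivity-bias parcellation of the striatum.

Converts a two-channel score map into per-voxel connectivity-bias fractions
(the share of the summed tractographic score attributable to each composite
target) and labels voxels striosome-like or matrix-like when the bias to one
target reaches the predominance threshold (default 0.87; a stricter 0.95
variant probes robustness).  The comparison is inclusive: a bias of exactly
0.87 labels the voxel.  Voxels with zero total score stay in the striatal
mask — they enter MCS/iSD denominators — but can never be labeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import ScoreMapPair
from .grid import VoxelGrid

LABEL_UNASSIGNED = 0
LABEL_STRIOSOME = 1
LABEL_MATRIX = 2

_COMPARTMENTS = ("striosome", "matrix")


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class ParcellationConfig:
    bias_threshold: float = 0.87

    def __post_init__(self) -> None:
        if not 0.5 < self.bias_threshold <= 1.0:
            raise ValueError(
                f"bias_threshold must be in (0.5, 1], got {self.bias_threshold}; "
                "at 0.5 or below the two compartment labels could collide"
            )


@dataclass
class BiasMap:
    """Per-voxel fraction of the summed score per target, where defined."""

    grid: VoxelGrid
    striosome: np.ndarray   # fraction in [0, 1]
    matrix: np.ndarray
    defined: np.ndarray     # bool: positive total score inside the mask
    mask: np.ndarray        # the striatal mask the bias was computed on


@dataclass
class LabelMap:
    grid: VoxelGrid
    labels: np.ndarray      # int8, LABEL_* codes inside the mask, 0 outside
    mask: np.ndarray

    def count(self, label: int) -> int:
        return int((self.labels[self.mask] == label).sum())


def compute_bias(scores: ScoreMapPair, mask: np.ndarray) -> BiasMap:
    """Per-voxel connectivity bias toward each composite target.

    ``fraction_i = score_i / (score_striosome + score_matrix)``; voxels with
    zero total score are marked undefined (they stay in the mask but are
    excluded from labeling).
    """
    if scores.striosome.shape != mask.shape:
        raise DataError("score maps and mask must share one grid")
    if (scores.striosome < 0).any() or (scores.matrix < 0).any():
        raise DataError("negative tractographic score")
    total = scores.striosome + scores.matrix
    defined = mask & (total > 0)
    s_frac = np.zeros(mask.shape, dtype=float)
    m_frac = np.zeros(mask.shape, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        s_frac[defined] = scores.striosome[defined] / total[defined]
        m_frac[defined] = scores.matrix[defined] / total[defined]
    return BiasMap(grid=scores.grid, striosome=s_frac, matrix=m_frac,
                   defined=defined, mask=mask.astype(bool))


def label_compartments(bias: BiasMap, config: ParcellationConfig) -> LabelMap:
    """Label voxels whose bias to one target is at least the threshold."""
    thr = config.bias_threshold
    labels = np.zeros(bias.mask.shape, dtype=np.int8)
    labels[bias.defined & (bias.striosome >= thr)] = LABEL_STRIOSOME
    labels[bias.defined & (bias.matrix >= thr)] = LABEL_MATRIX
    return LabelMap(grid=bias.grid, labels=labels, mask=bias.mask)


def compartment_volume(
    labels: LabelMap,
    grid: VoxelGrid | None = None,
    hemisphere: np.ndarray | None = None,
) -> dict[str, dict[str, float]]:
    """Labeled compartment volumes in cm³.

    Returns ``{compartment: {"left": v, "right": v, "total": v}}``.  When no
    hemisphere coding is given, everything is reported under "total".
    """
    grid = grid or labels.grid
    vox_cm3 = grid.voxel_volume_mm3 / 1000.0
    out: dict[str, dict[str, float]] = {}
    for name, code in (("striosome", LABEL_STRIOSOME), ("matrix", LABEL_MATRIX)):
        hit = labels.mask & (labels.labels == code)
        if hemisphere is None:
            out[name] = {"total": float(hit.sum() * vox_cm3)}
        else:
            left = float((hit & (hemisphere == 1)).sum() * vox_cm3)
            right = float((hit & (hemisphere == 2)).sum() * vox_cm3)
            out[name] = {"left": left, "right": right, "total": left + right}
    return out
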