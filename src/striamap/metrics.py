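"""Compartment connectivity metrics and reference-volume adjustment.

MCS (mean connectivity score): sum of all striatal-mask voxels' scores to a
target divided by the number of mask voxels.  iSD (index of streamline
density): percentage of mask voxels with any streamline to the target
(score > 0; distance correction preserves positivity, so the convention is
robust to real-valued scores).  Compartment volumes are adjusted to the
control-group mean total striatal mask volume (TSMV) by

    volume_adjusted = volume_raw - beta * (TSMV_raw - TSMV_mean)

with beta the ordinary-least-squares slope of raw volume on TSMV in controls
only, fitted separately for each adjusted measure.  MCS and iSD are computed
on raw scores; only volumes are adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import parcellation
from .cohort import Cohort
from .parcellation import ParcellationConfig


class EmptyMaskError(ValueError):
    pass


def mean_connectivity_score(scores: np.ndarray, mask: np.ndarray) -> float:
    """Sum of in-mask scores divided by the mask voxel count."""
    n = int(mask.sum())
    if n == 0:
        raise EmptyMaskError("MCS undefined on an empty mask")
    return float(scores[mask].sum() / n)


def index_streamline_density(scores: np.ndarray, mask: np.ndarray) -> float:
    """Percentage of mask voxels with a positive score (any streamline)."""
    n = int(mask.sum())
    if n == 0:
        raise EmptyMaskError("iSD undefined on an empty mask")
    return float(100.0 * (scores[mask] > 0).sum() / n)


@dataclass(frozen=True)
class AdjustmentModel:
    """Eq.-style control-referenced volume adjustment for one measure."""

    beta: float
    tsmv_mean: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if self.tsmv_mean <= 0:
            raise ValueError("TSMV mean must be positive")


def fit_adjustment(raw_volumes, tsmv) -> AdjustmentModel:
    """OLS slope of raw volume on TSMV over control subjects.

    ``tsmv_mean`` is the control mean; requires >= 3 controls with TSMV
    variance > 0.
    """
    v = np.asarray(raw_volumes, dtype=float)
    t = np.asarray(tsmv, dtype=float)
    if v.shape != t.shape or v.ndim != 1 or v.size < 3:
        raise ValueError("need >= 3 paired (volume, TSMV) control rows")
    tc = t - t.mean()
    denom = float(np.dot(tc, tc))
    if denom == 0:
        raise ValueError("zero TSMV variance in controls")
    beta = float(np.dot(tc, v - v.mean()) / denom)
    return AdjustmentModel(beta=beta, tsmv_mean=float(t.mean()))


def adjust_volume(raw: float, tsmv_raw: float, model: AdjustmentModel) -> float:
    return float(raw - model.beta * (tsmv_raw - model.tsmv_mean))


# ---------------------------------------------------------------------------
# cohort-level metric tables
# ---------------------------------------------------------------------------

def subject_metrics(
    subject, config: ParcellationConfig | None = None
) -> dict[str, float]:
    """Raw per-subject compartment metrics (volumes cm³, MCS, iSD %).

    Bilateral MCS/iSD are the mean of the hemispheric values (each hemisphere
    uses its own mask voxel count as denominator); volumes are summed.
    """
    config = config or ParcellationConfig()
    field, scores = subject.field, subject.scores
    bias = parcellation.compute_bias(scores, field.mask)
    labels = parcellation.label_compartments(bias, config)
    vols = parcellation.compartment_volume(labels, field.grid, field.hemisphere)

    out: dict[str, float] = {}
    for comp in ("striosome", "matrix"):
        ch = getattr(scores, comp)
        for side, key in (("L", "left"), ("R", "right")):
            hm = field.hemi_mask(side)
            out[f"{comp}_vol_{key}"] = vols[comp][key]
            out[f"{comp}_mcs_{key}"] = mean_connectivity_score(ch, hm)
            out[f"{comp}_isd_{key}"] = index_streamline_density(ch, hm)
        out[f"{comp}_vol_total"] = vols[comp]["total"]
        out[f"{comp}_mcs"] = (out[f"{comp}_mcs_left"] + out[f"{comp}_mcs_right"]) / 2
        out[f"{comp}_isd"] = (out[f"{comp}_isd_left"] + out[f"{comp}_isd_right"]) / 2
    return out


#: volume columns that receive a control-referenced TSMV adjustment
ADJUSTED_MEASURES = (
    "striosome_vol_total", "matrix_vol_total",
    "striosome_vol_left", "striosome_vol_right",
    "matrix_vol_left", "matrix_vol_right",
)


def cohort_metrics(
    cohort: Cohort, config: ParcellationConfig | None = None
) -> pd.DataFrame:
    """Per-subject metrics table with TSMV-adjusted volume columns.

    Adjustment betas are fitted on controls, one per measure; per-hemisphere
    volumes are adjusted against the *total* TSMV (halved reference for each
    hemisphere's share), mirroring how the side analyses reference the total
    striatal mask volume.
    """
    config = config or ParcellationConfig()
    rows = []
    for s in cohort.subjects:
        r = s.record
        row = {"id": r.id, "group": r.group, "age": r.age,
               "sex": r.sex, "tsmv_cm3": r.tsmv_cm3, "sbr_mean": r.sbr_mean,
               "sbr_left": r.sbr_left, "sbr_right": r.sbr_right}
        row.update(subject_metrics(s, config))
        rows.append(row)
    df = pd.DataFrame(rows)
    ctrl = df[df["group"] == "control"]
    tsmv = df["tsmv_cm3"].to_numpy()
    for col in ADJUSTED_MEASURES:
        model = fit_adjustment(ctrl[col].to_numpy(), ctrl["tsmv_cm3"].to_numpy())
        df[col + "_adj"] = [
            adjust_volume(v, t, model) for v, t in zip(df[col].to_numpy(), tsmv)
        ]
    return df
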