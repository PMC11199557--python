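"""Synthetic cohort generation.

Produces complete synthetic cohorts — per-subject striatal voxel masks with a
latent striosome/matrix compartment field, two-channel tractographic score
maps, and a covariate table (demographics, DAT-SPECT putaminal SBR, MoCA,
item-level MDS-UPDRS III) — with the statistical structure the downstream
parcellation and inference stages assume.

The score model is a three-layer mixture, per voxel:

1. *Bias layer.* Each voxel carries a latent striosome-ward bias (high in
   striosome islands, low in matrix).  Nigrostriatal denervation (the gap
   between a reference SBR and the hemisphere's putaminal SBR) shifts the
   bias toward matrix; a logit-normal voxel jitter creates the scatter of
   near-threshold voxels the bias thresholding acts on.
2. *Reach layer.* Whether a voxel emits any streamline score to a target at
   all is Bernoulli (zero-inflation); this is what gives iSD values near 50%
   rather than 100%.  Cross-target reach is conditioned on own-target reach,
   with a small "leak" of voxels connected only to the opposite target.
3. *Magnitude layer.* Scores given reach are Poisson, scaled by subject- and
   hemisphere-level lognormal/Gaussian random effects and by the SBR-driven
   matrix amplification.

Default parameter values are calibrated (analytically from the mixture
moments, then refined by simulation) so that a default cohort reproduces the
reference control-group compartment composition (~15.4% striosome-like
voxels, matrix iSD ~51%, matrix MCS ~4.5e3) and the disease-effect sizes
(PD matrix-like volume excess, negative SBR/matrix-MCS partial correlation,
low-SBR-side striosome reduction).  See docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .grid import VoxelGrid

GROUPS = ("control", "iRBD", "PD")

# MDS-UPDRS III item catalogue.  Codes follow the scale's part-3 numbering
# with limb/side suffixes: 3a neck, 3b/3c upper R/L, 3d/3e lower R/L rigidity;
# 4-8 and 15-16 carry R/L suffixes; 17a-d are rest-tremor amplitude RUE, LUE,
# RLE, LLE and 17e is lip/jaw.
RIGHT_ITEMS = (
    "3b", "3d", "4R", "5R", "6R", "7R", "8R", "15R", "16R", "17a", "17c",
)
LEFT_ITEMS = (
    "3c", "3e", "4L", "5L", "6L", "7L", "8L", "15L", "16L", "17b", "17d",
)
MIDLINE_ITEMS = (
    "1", "2", "3a", "9", "10", "11", "12", "13", "14", "17e", "18",
)
ALL_ITEMS = MIDLINE_ITEMS + RIGHT_ITEMS + LEFT_ITEMS

# generation slots per motor subscore (item 9 is generated once, under axial)
_SUBSCORE_SLOTS = {
    "tremor": ("15R", "15L", "16R", "16L", "17a", "17b", "17c", "17d", "17e", "18"),
    "bradykinesia": ("2", "4R", "4L", "5R", "5L", "6R", "6L", "7R", "7L", "8R", "8L", "14"),
    "rigidity": ("3a", "3b", "3c", "3d", "3e"),
    "axial": ("1", "9", "10", "11", "12", "13"),
}


class ConfigError(ValueError):
    """Invalid cohort configuration."""


class SizingError(ValueError):
    """The configured striatal volume does not fit on the grid."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gaussian:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError(f"negative SD: {self.sd}")


@dataclass(frozen=True)
class GroupDemographics:
    age: Gaussian
    male_fraction: float
    moca: Gaussian
    tiv_cm3: Gaussian
    tsmv_cm3: Gaussian
    duration_years: Gaussian | None = None


def _default_demographics() -> dict[str, GroupDemographics]:
    # reference-cohort calibration: age/sex/MoCA/TSMV per diagnostic group;
    # TIV is a generator-supplied covariate (typical adult values)
    return {
        "control": GroupDemographics(
            age=Gaussian(60.4, 9.1), male_fraction=30 / 45,
            moca=Gaussian(25.6, 2.4), tiv_cm3=Gaussian(1450.0, 130.0),
            tsmv_cm3=Gaussian(14.3, 1.7),
        ),
        "iRBD": GroupDemographics(
            age=Gaussian(66.8, 6.6), male_fraction=48 / 56,
            moca=Gaussian(23.6, 2.9), tiv_cm3=Gaussian(1450.0, 130.0),
            tsmv_cm3=Gaussian(14.1, 1.7), duration_years=Gaussian(7.0, 5.2),
        ),
        "PD": GroupDemographics(
            age=Gaussian(60.0, 12.1), male_fraction=47 / 72,
            moca=Gaussian(24.8, 3.0), tiv_cm3=Gaussian(1450.0, 130.0),
            tsmv_cm3=Gaussian(14.8, 1.7), duration_years=Gaussian(2.1, 1.8),
        ),
    }


@dataclass(frozen=True)
class SbrModel:
    """Putaminal SBR distribution: subject mean, lognormal side asymmetry."""

    group: dict[str, Gaussian | None] = dc_field(
        default_factory=lambda: {
            "control": None,          # controls have no DAT-SPECT
            "iRBD": Gaussian(2.3, 0.8),
            "PD": Gaussian(1.6, 0.8),
        }
    )
    # mean relative side difference (|L-R| / mean), calibrated to the
    # reported average side asymmetry of ~13.8%
    side_asymmetry_fraction: float = 0.138
    side_asymmetry_sigma: float = 0.4
    reference_sbr: float = 2.8       # implied healthy baseline; deficit = ref - SBR
    n_irbd_missing: int = 3          # iRBD subjects without usable DAT-SPECT
    floor: float = 0.2


@dataclass(frozen=True)
class GeometryConfig:
    grid_dims: tuple[int, int, int] = (24, 26, 22)
    voxel_size_mm: float = 2.0
    striosome_fraction: float = 0.156 # latent target fraction per hemisphere
    island_radius_mm: float = 3.0
    spatial_bias: float = 1.5          # rostro-ventro-medial island placement weight
    latent_predominance: float = 0.95  # latent own-target bias of either compartment
    hemisphere_aspect: tuple[float, float, float] = (1.4, 1.15, 1.0)


@dataclass(frozen=True)
class ScoreModel:
    """Reach probabilities and score magnitudes of the mixture (controls)."""

    samples_per_voxel: float = 5000.0   # tracker sampling budget the scales mimic
    # mean total score of a reaching voxel, per latent compartment, at the
    # default sampling budget (distance-corrected scores exceed raw counts)
    matrix_voxel_score_mean: float = 9830.0
    striosome_voxel_score_mean: float = 1850.0
    leak_score_mean: float = 300.0
    # reach (zero-inflation) structure
    q_own_matrix: float = 0.515
    q_own_striosome: float = 0.93
    q_cross_matrix: float = 0.422     # P(strio reach | matrix voxel reaches matrix)
    q_cross_striosome: float = 0.52  # P(matrix reach | strio voxel reaches strio)
    q_leak: float = 0.05              # P(cross reach | own target not reached)


@dataclass(frozen=True)
class EffectsConfig:
    """Disease-effect slopes and noise dispersions.

    Deficit is ``reference_sbr - SBR_hemisphere`` (0 for controls); the
    *side* slopes act on the within-subject relative deficit (hemisphere
    deficit minus the subject mean), so they create paired side differences
    without inducing between-subject SBR correlations.
    """

    matrix_reach_sbr_slope: float = 0.019    # reach probability per deficit unit
    matrix_score_sbr_slope: float = 0.10     # score magnitude fraction per deficit unit
    bias_sbr_slope: float = 0.02             # latent bias shift toward matrix per unit
    pd_matrix_volume_offset_cm3: float = 0.0 # extra PD matrix volume beyond SBR-mediated
    striosome_side_reach_slope: float = 0.64
    striosome_side_score_slope: float = 0.8
    matrix_side_reach_slope: float = 0.1
    # dispersions
    subject_score_sigma: float = 0.36   # lognormal sigma on per-channel magnitudes
    subject_reach_sd: float = 0.06      # Gaussian jitter on reach probabilities
    hemisphere_reach_sd: float = 0.04   # per-hemisphere reach jitter
    bias_sigma: float = 0.8             # logit-scale voxelwise bias jitter

    def __post_init__(self) -> None:
        for name in ("subject_score_sigma", "subject_reach_sd",
                     "hemisphere_reach_sd", "bias_sigma"):
            if getattr(self, name) < 0:
                raise ConfigError(f"negative dispersion: {name}")

    @property
    def deterministic(self) -> bool:
        """All dispersions zero: scores are exact expectations of the bias."""
        return (self.subject_score_sigma == 0 and self.subject_reach_sd == 0
                and self.hemisphere_reach_sd == 0 and self.bias_sigma == 0)


@dataclass(frozen=True)
class ClinicalConfig:
    """MDS-UPDRS III subscore means per group and SBR coupling."""

    subscore_means: dict[str, dict[str, float]] = dc_field(
        default_factory=lambda: {
            "control": {"tremor": 0.9, "bradykinesia": 1.9, "rigidity": 0.3, "axial": 0.2},
            "iRBD": {"tremor": 2.1, "bradykinesia": 3.5, "rigidity": 0.2, "axial": 1.0},
            "PD": {"tremor": 6.3, "bradykinesia": 18.2, "rigidity": 4.1, "axial": 2.5},
        }
    )
    severity_sigma: float = 0.4   # lognormal subject severity multiplier
    sbr_coupling: float = 2.0     # lateralized item rate slope per contralateral
    #                               relative SBR deficit


@dataclass(frozen=True)
class CohortConfig:
    n_control: int = 45
    n_irbd: int = 56
    n_pd: int = 72
    seed: int = 0
    demographics: dict[str, GroupDemographics] = dc_field(default_factory=_default_demographics)
    sbr_model: SbrModel = dc_field(default_factory=SbrModel)
    geometry: GeometryConfig = dc_field(default_factory=GeometryConfig)
    score_model: ScoreModel = dc_field(default_factory=ScoreModel)
    effects: EffectsConfig = dc_field(default_factory=EffectsConfig)
    clinical: ClinicalConfig = dc_field(default_factory=ClinicalConfig)

    def __post_init__(self) -> None:
        for n in (self.n_control, self.n_irbd, self.n_pd):
            if n < 2:
                raise ConfigError("group counts must be >= 2")
        if not 0 < self.geometry.striosome_fraction < 1:
            raise ConfigError("striosome_fraction must be in (0, 1)")

    def null(self) -> "CohortConfig":
        """Copy with all disease-effect slopes and couplings set to zero."""
        return dataclasses.replace(
            self,
            effects=dataclasses.replace(
                self.effects,
                matrix_reach_sbr_slope=0.0, matrix_score_sbr_slope=0.0,
                bias_sbr_slope=0.0, pd_matrix_volume_offset_cm3=0.0,
                striosome_side_reach_slope=0.0, striosome_side_score_slope=0.0,
                matrix_side_reach_slope=0.0,
            ),
            clinical=dataclasses.replace(self.clinical, sbr_coupling=0.0),
        )

    def grid(self) -> VoxelGrid:
        g = self.geometry
        return VoxelGrid(g.grid_dims, (g.voxel_size_mm,) * 3)


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    id: str
    group: str
    age: float
    sex: str                       # "M" / "F"
    tiv_cm3: float
    tsmv_left_cm3: float
    tsmv_right_cm3: float
    sbr_left: float                # NaN when no DAT-SPECT
    sbr_right: float
    moca: int
    items: dict[str, int]          # MDS-UPDRS III item scores, 0..4
    duration_years: float          # NaN when not applicable

    @property
    def tsmv_cm3(self) -> float:
        return self.tsmv_left_cm3 + self.tsmv_right_cm3

    @property
    def sbr_mean(self) -> float:
        return (self.sbr_left + self.sbr_right) / 2.0

    @property
    def updrs3_total(self) -> int:
        return int(sum(self.items.values()))

    def subscore(self, name: str) -> int:
        from . import stats  # item->subscore catalogue lives with its consumer
        return int(sum(self.items[c] for c in stats.SUBSCORE_ITEM_CODES[name]))


@dataclass
class LatentCompartmentField:
    """Ground-truth compartment geometry of one subject."""

    grid: VoxelGrid
    hemisphere: np.ndarray      # int8: 0 outside, 1 left, 2 right
    striosome: np.ndarray       # bool, inside mask only
    bias: np.ndarray            # latent striosome-ward bias in [0, 1]
    n_islands: tuple[int, int]

    @property
    def mask(self) -> np.ndarray:
        return self.hemisphere > 0

    def hemi_mask(self, side: str) -> np.ndarray:
        return self.hemisphere == (1 if side == "L" else 2)

    @property
    def striosome_fraction(self) -> float:
        m = self.mask
        return float(self.striosome[m].mean())


@dataclass
class ScoreMapPair:
    """Voxelwise tractographic scores to the two composite target sets."""

    grid: VoxelGrid
    striosome: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.striosome.shape != self.matrix.shape:
            raise ValueError("score channels must share one grid")
        if (self.striosome < 0).any() or (self.matrix < 0).any():
            raise ValueError("tractographic scores must be nonnegative")


@dataclass
class SyntheticSubject:
    record: SubjectRecord
    field: LatentCompartmentField
    scores: ScoreMapPair


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list[SyntheticSubject]

    @property
    def grid(self) -> VoxelGrid:
        return self.config.grid()

    def table(self) -> pd.DataFrame:
        """Covariate table, one row per subject."""
        rows = []
        for s in self.subjects:
            r = s.record
            rows.append({
                "id": r.id, "group": r.group, "age": r.age, "sex": r.sex,
                "tiv_cm3": r.tiv_cm3, "tsmv_cm3": r.tsmv_cm3,
                "tsmv_left_cm3": r.tsmv_left_cm3, "tsmv_right_cm3": r.tsmv_right_cm3,
                "sbr_left": r.sbr_left, "sbr_right": r.sbr_right,
                "sbr_mean": r.sbr_mean, "moca": r.moca,
                "duration_years": r.duration_years,
                "updrs3_total": r.updrs3_total,
                "updrs3_tremor": r.subscore("tremor"),
                "updrs3_bradykinesia": r.subscore("bradykinesia"),
                "updrs3_rigidity": r.subscore("rigidity"),
                "updrs3_axial": r.subscore("axial"),
            })
        return pd.DataFrame(rows)

    def items_table(self) -> pd.DataFrame:
        rows = [{"id": s.record.id, **{c: s.record.items[c] for c in ALL_ITEMS}}
                for s in self.subjects]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def generate_geometry(
    config: CohortConfig,
    grid: VoxelGrid,
    rng: np.random.Generator,
    tsmv_cm3: float | None = None,
) -> LatentCompartmentField:
    """Build per-hemisphere striatal masks and the latent compartment field.

    Each hemisphere is one contiguous ellipsoid-like blob of exactly the
    voxel count implied by the requested total striatal mask volume, split
    evenly across hemispheres.  Striosome islands (balls of the configured
    radius) are placed with a rostro-ventro-medial spatial preference until
    the configured striosome voxel fraction is met exactly (the last island
    is truncated), so the island count is emergent.
    """
    geo = config.geometry
    if tsmv_cm3 is None:
        tsmv_cm3 = config.demographics["control"].tsmv_cm3.mean
    vox_mm3 = grid.voxel_volume_mm3
    n_per_hemi = int(round(tsmv_cm3 * 1000.0 / vox_mm3 / 2.0))
    if n_per_hemi < 1:
        raise SizingError("requested TSMV smaller than one voxel per hemisphere")

    world = grid.world_coordinates()           # dims + (3,)
    x = world[..., 0]
    hemisphere = np.zeros(grid.dims, dtype=np.int8)
    striosome = np.zeros(grid.dims, dtype=bool)
    n_islands: list[int] = []

    for side_code, side_sel in ((1, x < 0), (2, x > 0)):
        capacity = int(side_sel.sum())
        if n_per_hemi > capacity:
            need = int(np.ceil((2 * n_per_hemi / (grid.dims[1] * grid.dims[2]))))
            raise SizingError(
                f"TSMV {tsmv_cm3:.1f} cm3 needs {n_per_hemi} voxels per hemisphere "
                f"but the half-grid holds {capacity}; increase grid dims "
                f"(first axis to >= {max(grid.dims[0], 2 * need)})"
            )
        coords = world[side_sel]               # (n, 3)
        centre = coords.mean(axis=0)
        # anisotropic distance -> ellipsoidal blob; picking the n smallest
        # distances guarantees the exact count and contiguity
        aspect = np.asarray(geo.hemisphere_aspect)
        d2 = (((coords - centre) / aspect) ** 2).sum(axis=1)
        order = np.argsort(d2, kind="stable")[:n_per_hemi]
        flat_side = np.flatnonzero(side_sel.ravel())
        chosen = flat_side[order]
        hemisphere.ravel()[chosen] = side_code

        striosome_sel, placed = _place_islands(coords[order], geo, rng, side=side_code)
        striosome.ravel()[chosen[striosome_sel]] = True
        n_islands.append(placed)

    bias = np.zeros(grid.dims, dtype=float)
    bias[(hemisphere > 0) & striosome] = geo.latent_predominance
    bias[(hemisphere > 0) & ~striosome] = 1.0 - geo.latent_predominance
    return LatentCompartmentField(
        grid=grid, hemisphere=hemisphere, striosome=striosome, bias=bias,
        n_islands=(n_islands[0], n_islands[1]),
    )


def _place_islands(
    coords: np.ndarray, geo: GeometryConfig, rng: np.random.Generator, side: int
) -> tuple[np.ndarray, int]:
    """Select striosome voxels (mask into ``coords``) as spatially biased islands."""
    n = coords.shape[0]
    target = int(round(geo.striosome_fraction * n))
    chosen = np.zeros(n, dtype=bool)
    if target == 0:
        return chosen, 0

    # rostro-ventro-medial placement weight: +y rostral, -z ventral,
    # medial = small |x| (toward the midline)
    span = coords.max(axis=0) - coords.min(axis=0)
    span[span == 0] = 1.0
    rel = (coords - coords.min(axis=0)) / span          # in [0, 1] per axis
    medial = 1.0 - rel[:, 0] if side == 2 else rel[:, 0]
    weight = np.exp(geo.spatial_bias * (rel[:, 1] + (1.0 - rel[:, 2]) + medial))

    remaining = target
    placed = 0
    r = geo.island_radius_mm
    while remaining > 0:
        free = ~chosen
        w = weight * free
        total = w.sum()
        if total <= 0:
            break
        centre_idx = rng.choice(n, p=w / total)
        dist = np.linalg.norm(coords - coords[centre_idx], axis=1)
        ball = np.flatnonzero(free & (dist <= r + 1e-9))
        ball = ball[np.argsort(dist[ball], kind="stable")]
        take = ball[:remaining]
        chosen[take] = True
        remaining -= take.size
        placed += 1
    return chosen, placed


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def _hemisphere_deficits(record: SubjectRecord, sbr: SbrModel) -> tuple[float, float]:
    """(deficit_left, deficit_right); 0 when the subject has no SBR."""
    if np.isnan(record.sbr_left) or np.isnan(record.sbr_right):
        return 0.0, 0.0
    d_l = max(0.0, sbr.reference_sbr - record.sbr_left)
    d_r = max(0.0, sbr.reference_sbr - record.sbr_right)
    return d_l, d_r


def generate_scores(
    field: LatentCompartmentField,
    record: SubjectRecord,
    config: CohortConfig,
    rng: np.random.Generator,
) -> ScoreMapPair:
    """Realise a ScoreMapPair from the latent field for one subject.

    With all dispersions at zero the maps are exact expectations: every mask
    voxel scores ``samples_per_voxel`` split by its (possibly SBR-shifted)
    latent bias, so the realised bias equals the latent bias.
    """
    sm = config.score_model
    eff = config.effects
    scale = sm.samples_per_voxel / 5000.0
    s_map = np.zeros(field.grid.dims, dtype=float)
    m_map = np.zeros(field.grid.dims, dtype=float)
    d_l, d_r = _hemisphere_deficits(record, config.sbr_model)
    d_mean = (d_l + d_r) / 2.0

    pd_offset_q = 0.0
    if record.group == "PD" and eff.pd_matrix_volume_offset_cm3:
        # convert a volume offset to a reach-probability shift on the mask
        lab_per_q = 0.95 * (1 - field.striosome_fraction) * (
            field.mask.sum() * field.grid.voxel_volume_mm3 / 1000.0)
        pd_offset_q = eff.pd_matrix_volume_offset_cm3 / max(lab_per_q, 1e-9)

    if eff.deterministic:
        total = sm.samples_per_voxel
        for side, d_h in (("L", d_l), ("R", d_r)):
            hm = field.hemi_mask(side)
            p = np.clip(field.bias[hm] - eff.bias_sbr_slope * d_h, 0.0, 1.0)
            s_map[hm] = total * p
            m_map[hm] = total * (1.0 - p)
        return ScoreMapPair(field.grid, s_map, m_map)

    # subject-level random effects (per channel, shared across hemispheres)
    g_s, g_m = np.exp(eff.subject_score_sigma * rng.standard_normal(2))
    u_s, u_m = eff.subject_reach_sd * rng.standard_normal(2)

    for side, d_h in (("L", d_l), ("R", d_r)):
        hm = field.hemi_mask(side)
        nvox = int(hm.sum())
        if nvox == 0:
            continue
        rel_d = d_h - d_mean
        h_s, h_m = eff.hemisphere_reach_sd * rng.standard_normal(2)
        strio = field.striosome[hm]

        # bias layer
        b = np.clip(field.bias[hm] - eff.bias_sbr_slope * d_h, 1e-6, 1 - 1e-6)
        logit = np.log(b / (1 - b)) + eff.bias_sigma * rng.standard_normal(nvox)
        p = 1.0 / (1.0 + np.exp(-logit))

        # reach layer; striosome reach falls and matrix reach rises on the
        # more denervated side (+rel_d)
        q_own = np.where(
            strio,
            np.clip(sm.q_own_striosome
                    * (1 - eff.striosome_side_reach_slope * rel_d)
                    + u_s + h_s, 0, 1),
            np.clip(sm.q_own_matrix + eff.matrix_reach_sbr_slope * d_h
                    + eff.matrix_side_reach_slope * rel_d
                    + pd_offset_q + u_m + h_m, 0, 1),
        )
        reach_own = rng.random(nvox) < q_own
        q_cross = np.where(
            reach_own,
            np.where(strio, sm.q_cross_striosome, sm.q_cross_matrix),
            sm.q_leak,
        )
        reach_cross = rng.random(nvox) < q_cross

        # magnitude layer
        lam = np.where(strio,
                       sm.striosome_voxel_score_mean,
                       sm.matrix_voxel_score_mean) * scale
        strio_factor = np.clip(1 - eff.striosome_side_score_slope * rel_d, 0, None)
        matrix_factor = 1 + eff.matrix_score_sbr_slope * d_h
        reach_s = np.where(strio, reach_own, reach_cross)
        reach_m = np.where(strio, reach_cross, reach_own)
        leak = sm.leak_score_mean * scale
        # own-only voxels put their whole budget in the own channel; voxels
        # reaching only the cross target carry the small leak magnitude
        lam_s = np.where(strio,
                         np.where(reach_m, lam * p, lam),
                         np.where(reach_m, lam * p, leak))
        lam_m = np.where(strio,
                         np.where(reach_s, lam * (1 - p), leak),
                         np.where(reach_s, lam * (1 - p), lam))
        s_vals = rng.poisson(lam_s * g_s * strio_factor) * reach_s
        m_vals = rng.poisson(lam_m * g_m * matrix_factor) * reach_m
        s_map[hm] = s_vals
        m_map[hm] = m_vals

    return ScoreMapPair(field.grid, s_map, m_map)


# ---------------------------------------------------------------------------
# subject covariates
# ---------------------------------------------------------------------------

def _draw_record(
    group: str, idx: int, config: CohortConfig, rng: np.random.Generator,
    sbr_missing: bool,
) -> SubjectRecord:
    demo = config.demographics[group]
    sbrm = config.sbr_model
    age = float(np.clip(rng.normal(demo.age.mean, demo.age.sd), 18.0, 95.0))
    sex = "M" if rng.random() < demo.male_fraction else "F"
    tiv = float(max(rng.normal(demo.tiv_cm3.mean, demo.tiv_cm3.sd), 900.0))
    tsmv = float(max(rng.normal(demo.tsmv_cm3.mean, demo.tsmv_cm3.sd), 6.0))
    moca = int(np.clip(round(rng.normal(demo.moca.mean, demo.moca.sd)), 0, 30))
    # split TSMV across hemispheres with a small asymmetry
    split = float(np.clip(rng.normal(0.5, 0.015), 0.42, 0.58))
    tsmv_l, tsmv_r = tsmv * split, tsmv * (1 - split)

    sbr_spec = sbrm.group.get(group)
    if sbr_spec is None or sbr_missing:
        sbr_l = sbr_r = float("nan")
    else:
        mean_sbr = max(rng.normal(sbr_spec.mean, sbr_spec.sd), sbrm.floor)
        mu = np.log(sbrm.side_asymmetry_fraction) - sbrm.side_asymmetry_sigma ** 2 / 2
        delta = float(rng.lognormal(mu, sbrm.side_asymmetry_sigma))
        delta = min(delta, 1.5)
        lo = mean_sbr * (1 - delta / 2)
        hi = mean_sbr * (1 + delta / 2)
        if rng.random() < 0.5:
            sbr_l, sbr_r = lo, hi
        else:
            sbr_l, sbr_r = hi, lo
        sbr_l, sbr_r = max(sbr_l, sbrm.floor), max(sbr_r, sbrm.floor)

    if demo.duration_years is None:
        duration = float("nan")
    else:
        duration = float(max(
            rng.normal(demo.duration_years.mean, demo.duration_years.sd), 0.1))

    rec = SubjectRecord(
        id=f"sub-{idx:04d}", group=group, age=age, sex=sex, tiv_cm3=tiv,
        tsmv_left_cm3=tsmv_l, tsmv_right_cm3=tsmv_r,
        sbr_left=sbr_l, sbr_right=sbr_r, moca=moca, items={},
        duration_years=duration,
    )
    rec.items = _draw_items(rec, config, rng)
    return rec


def _draw_items(
    record: SubjectRecord, config: CohortConfig, rng: np.random.Generator
) -> dict[str, int]:
    clin = config.clinical
    means = clin.subscore_means[record.group]
    sev = float(np.exp(clin.severity_sigma * rng.standard_normal()
                       - clin.severity_sigma ** 2 / 2))
    d_l, d_r = _hemisphere_deficits(record, config.sbr_model)
    d_mean = (d_l + d_r) / 2.0
    # body side is contralateral to the hemisphere: right body <- left hemi
    asym = {"R": d_l - d_mean, "L": d_r - d_mean}
    items: dict[str, int] = {}
    for sub, slots in _SUBSCORE_SLOTS.items():
        p_base = means.get(sub, 0.0) / (4.0 * len(slots))
        for code in slots:
            p = p_base * sev
            if code in RIGHT_ITEMS:
                p *= 1 + clin.sbr_coupling * asym["R"]
            elif code in LEFT_ITEMS:
                p *= 1 + clin.sbr_coupling * asym["L"]
            items[code] = int(rng.binomial(4, float(np.clip(p, 0.0, 1.0))))
    return items


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full synthetic cohort.

    Each subject draws from an independent counter-derived substream
    (seeded by ``(config.seed, subject_index)``), so changing a group count
    never perturbs earlier subjects and identical configs are bit-identical.
    """
    grid = config.grid()
    groups = (["control"] * config.n_control + ["iRBD"] * config.n_irbd
              + ["PD"] * config.n_pd)
    n_missing = config.sbr_model.n_irbd_missing
    irbd_seen = 0
    subjects: list[SyntheticSubject] = []
    for idx, group in enumerate(groups):
        rng = np.random.default_rng([config.seed, idx])
        missing = False
        if group == "iRBD":
            irbd_seen += 1
            missing = irbd_seen > config.n_irbd - n_missing
        record = _draw_record(group, idx, config, rng, sbr_missing=missing)
        field = generate_geometry(config, grid, rng, tsmv_cm3=record.tsmv_cm3)
        # keep the recorded TSMV consistent with the discrete voxel mask
        vol_l = field.hemi_mask("L").sum() * grid.voxel_volume_mm3 / 1000.0
        vol_r = field.hemi_mask("R").sum() * grid.voxel_volume_mm3 / 1000.0
        record.tsmv_left_cm3, record.tsmv_right_cm3 = float(vol_l), float(vol_r)
        scores = generate_scores(field, record, config, rng)
        subjects.append(SyntheticSubject(record, field, scores))
    return Cohort(config=config, subjects=subjects)
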