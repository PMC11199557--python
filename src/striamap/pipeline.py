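"""Pipeline orchestration: simulate → parcellate → metrics → analyze.

Binds the stages into one reproducible run: a fixed global seed makes every
stage deterministic, per-stage outputs land in the run directory as NIfTI
volumes and CSV tables (6 significant digits), and a provenance record
(tool version, config hash, seed, row/voxel counts) is emitted for every
run.  Stage subsets can resume from the volumes and tables a previous run
saved.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, metrics as metrics_mod, parcellation, stats
from .cohort import (
    ALL_ITEMS, Cohort, CohortConfig, LatentCompartmentField, ScoreMapPair,
    SubjectRecord, SyntheticSubject, generate_cohort,
)
from .parcellation import ParcellationConfig

STAGES = ("simulate", "parcellate", "metrics", "analyze")

#: analysis measures: (metrics-table column, report label)
MEASURES = (
    ("matrix_vol_total_adj", "Matrix-like volume [cm3]"),
    ("matrix_mcs", "Matrix-like MCS"),
    ("matrix_isd", "Matrix-like iSD [%]"),
    ("striosome_vol_total_adj", "Striosome-like volume [cm3]"),
    ("striosome_mcs", "Striosome-like MCS"),
    ("striosome_isd", "Striosome-like iSD [%]"),
)

_FMT = "%.6g"


class StageError(RuntimeError):
    pass


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    cohort: CohortConfig = dc_field(default_factory=CohortConfig)
    parcellation: ParcellationConfig = dc_field(default_factory=ParcellationConfig)
    age_match: bool = True
    drop_item9_overlap: bool = False
    write_maps: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.cohort = dataclasses.replace(self.cohort, seed=self.seed)


# ---------------------------------------------------------------------------
# analysis driver
# ---------------------------------------------------------------------------

def _hemi_column(measure: str, side: str) -> str:
    # matrix_vol_total_adj -> matrix_vol_{left,right}_adj; matrix_mcs -> matrix_mcs_left
    if measure.endswith("_vol_total_adj"):
        return measure.replace("_total_adj", f"_{side}_adj")
    return f"{measure}_{side}"


def _result_row(label: str, res: stats.AnalysisResult) -> dict:
    row = {"measure": label, "statistic": res.statistic, "p": res.p, "n": res.n}
    if res.effect_name:
        row[res.effect_name] = res.effect_size
    if isinstance(res.df, tuple):
        row["df1"], row["df2"] = res.df
    else:
        row["df"] = res.df
    return row


def analyze_cohort(
    metrics_df: pd.DataFrame,
    items_df: pd.DataFrame | None = None,
    age_match: bool = True,
    drop_item9_overlap: bool = False,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Run the full between-/within-subject statistical chain.

    Returns result tables keyed: ``group_comparison`` (ANCOVA with age/sex
    per measure, LSD post-hoc p values), ``sbr_correlations`` (partial
    correlations with mean putaminal SBR, pooled PD+iRBD with DAT-SPECT),
    ``sbr_side_comparison`` (paired t between low- and high-SBR
    hemispheres), ``lateralized_side_comparison`` (paired t between sides
    with lower/higher lateralized motor scores, PD, contralateral
    hemisphere values), ``motor_correlations`` and, when enabled,
    ``age_matched_sensitivity``.
    """
    df = metrics_df
    sex01 = stats.encode_sex(df["sex"])
    cov = np.column_stack([df["age"].to_numpy(float), sex01])

    # --- between-group ANCOVA with LSD post-hoc -------------------------
    rows = []
    for colname, label in MEASURES:
        res = stats.run_group_ancova(df[colname], df["group"], cov, name=colname)
        row = _result_row(label, res)
        for _, ph in res.posthoc.iterrows():
            row[f"p_{ph['a']}_vs_{ph['b']}"] = ph["p"]
        rows.append(row)
    tables = {"group_comparison": pd.DataFrame(rows)}

    # --- pooled PD+iRBD vs nigrostriatal denervation --------------------
    pooled = df[df["group"].isin(["PD", "iRBD"]) & df["sbr_mean"].notna()]
    if len(pooled) >= 8:   # partial correlation needs n > covariates + 2
        pcov = np.column_stack([pooled["age"].to_numpy(float),
                                stats.encode_sex(pooled["sex"])])
        rows = []
        for colname, label in MEASURES:
            res = stats.run_partial_correlation(
                pooled["sbr_mean"], pooled[colname], pcov, name=colname)
            rows.append(_result_row(label, res))
        tables["sbr_correlations"] = pd.DataFrame(rows)

    # --- paired comparison of low- vs high-SBR hemispheres --------------
    if len(pooled) >= 3:
        low_is_left = pooled["sbr_left"].to_numpy() < pooled["sbr_right"].to_numpy()
        rows = []
        sbr_lo = np.where(low_is_left, pooled["sbr_left"], pooled["sbr_right"])
        sbr_hi = np.where(low_is_left, pooled["sbr_right"], pooled["sbr_left"])
        res = stats.run_paired_side_comparison(sbr_lo, sbr_hi, name="sbr")
        rows.append({**_result_row("Putaminal SBR", res),
                     "mean_low": sbr_lo.mean(), "mean_high": sbr_hi.mean()})
        for colname, label in MEASURES:
            left = pooled[_hemi_column(colname, "left")].to_numpy(float)
            right = pooled[_hemi_column(colname, "right")].to_numpy(float)
            lo = np.where(low_is_left, left, right)
            hi = np.where(low_is_left, right, left)
            res = stats.run_paired_side_comparison(lo, hi, name=colname)
            rows.append({**_result_row(label, res),
                         "mean_low": lo.mean(), "mean_high": hi.mean()})
        tables["sbr_side_comparison"] = pd.DataFrame(rows)

    # --- lateralized motor-score side comparisons (PD) ------------------
    if items_df is not None:
        pd_df = df[df["group"] == "PD"]
        items_by_id = items_df.set_index("id")
        rows = []
        for family in ("total", "tremor", "rigidity", "bradykinesia"):
            lats = {}
            for sid in pd_df["id"]:
                item_map = items_by_id.loc[sid, list(ALL_ITEMS)].to_dict()
                lats[sid] = stats.compute_lateralized_scores(
                    item_map, family, drop_overlap=drop_item9_overlap)
            kept = pd_df[[not lats[s].excluded for s in pd_df["id"]]]
            if len(kept) < 2:
                continue
            # low body side -> contralateral hemisphere
            hemi_low = ["right" if lats[s].low_side == "L" else "left"
                        for s in kept["id"]]
            for colname, label in MEASURES:
                lo = np.array([kept.iloc[i][_hemi_column(colname, h)]
                               for i, h in enumerate(hemi_low)], dtype=float)
                hi = np.array([kept.iloc[i][_hemi_column(
                    colname, "left" if h == "right" else "right")]
                    for i, h in enumerate(hemi_low)], dtype=float)
                res = stats.run_paired_side_comparison(lo, hi, name=colname)
                rows.append({"score": family, **_result_row(label, res),
                             "mean_low": lo.mean(), "mean_high": hi.mean()})
        tables["lateralized_side_comparison"] = pd.DataFrame(rows)

        # partial correlations of measures with motor scores (PD)
        pd_cov = np.column_stack([pd_df["age"].to_numpy(float),
                                  stats.encode_sex(pd_df["sex"])])
        rows = []
        families = (("total", "tremor", "rigidity", "bradykinesia", "axial")
                    if len(pd_df) >= 8 else ())
        for family in families:
            codes = stats.subscore_item_codes(
                family if family != "total" else "total", drop_item9_overlap)
            score = items_by_id.loc[pd_df["id"], list(codes)].sum(axis=1).to_numpy(float)
            for colname, label in MEASURES:
                try:
                    res = stats.run_partial_correlation(
                        score, pd_df[colname], pd_cov, name=colname)
                except stats.DegenerateTestError:
                    continue
                rows.append({"score": family, **_result_row(label, res)})
        tables["motor_correlations"] = pd.DataFrame(rows)

    # --- age-matched PD vs iRBD sensitivity -----------------------------
    if age_match:
        pd_rows = df[df["group"] == "PD"].reset_index(drop=True)
        irbd_rows = df[df["group"] == "iRBD"].reset_index(drop=True)
        pairs = stats.age_match(
            pd_rows["age"], irbd_rows["age"], tolerance_years=5.0,
            rng=np.random.default_rng([seed, 977]))
        if len(pairs) >= 4:
            sub = pd.concat(
                [pd_rows.iloc[[i for i, _ in pairs]],
                 irbd_rows.iloc[[j for _, j in pairs]]], ignore_index=True)
            scov = np.column_stack([sub["age"].to_numpy(float),
                                    stats.encode_sex(sub["sex"])])
            rows = []
            for colname in ("matrix_vol_total_adj", "matrix_mcs"):
                res = stats.run_group_ancova(sub[colname], sub["group"], scov,
                                             name=colname)
                rows.append(_result_row(colname, res))
            t = pd.DataFrame(rows)
            t.insert(0, "n_matched_pairs", len(pairs))
            tables["age_matched_sensitivity"] = t
    return tables


def demographics_table(covariates: pd.DataFrame) -> pd.DataFrame:
    """Group comparisons of demographics and clinical covariates."""
    rows = []
    sex_tab = pd.crosstab(covariates["group"], covariates["sex"])
    res = stats.chi_squared_table(sex_tab.to_numpy(), name="sex")
    rows.append(_result_row("Male sex", res))
    res = stats.run_group_ancova(covariates["age"], covariates["group"], None,
                                 name="age")
    rows.append(_result_row("Age (years)", res))
    cov = np.column_stack([covariates["age"].to_numpy(float),
                           stats.encode_sex(covariates["sex"])])
    for col, label in (("moca", "MoCA"), ("updrs3_total", "MDS-UPDRS III"),
                       ("updrs3_tremor", "MDS-UPDRS III - tremor"),
                       ("updrs3_bradykinesia", "MDS-UPDRS III - bradykinesia"),
                       ("updrs3_rigidity", "MDS-UPDRS III - rigidity"),
                       ("updrs3_axial", "MDS-UPDRS III - axial")):
        res = stats.run_group_ancova(covariates[col], covariates["group"], cov,
                                     name=col)
        rows.append(_result_row(label, res))
    cov3 = np.column_stack([cov, covariates["tiv_cm3"].to_numpy(float)])
    res = stats.run_group_ancova(covariates["tsmv_cm3"], covariates["group"],
                                 cov3, name="tsmv")
    rows.append(_result_row("Total striatal seed mask volume (cm3)", res))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage runner
# ---------------------------------------------------------------------------

def _maps_dir(out: Path) -> Path:
    return out / "maps"


def _write_cohort(cohort: Cohort, out: Path, write_maps: bool) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cohort.table().to_csv(out / "covariates.csv", index=False, float_format=_FMT)
    cohort.items_table().to_csv(out / "items.csv", index=False)
    if not write_maps:
        return
    mdir = _maps_dir(out)
    mdir.mkdir(exist_ok=True)
    for s in cohort.subjects:
        sid = s.record.id
        grid = s.field.grid
        io.write_volume(mdir / f"{sid}_hemisphere.nii.gz",
                        s.field.hemisphere.astype(np.int8), grid)
        io.write_volume(mdir / f"{sid}_striosome_latent.nii.gz",
                        s.field.striosome.astype(np.uint8), grid)
        io.write_volume(mdir / f"{sid}_score_striosome.nii.gz",
                        s.scores.striosome.astype(np.float32), grid)
        io.write_volume(mdir / f"{sid}_score_matrix.nii.gz",
                        s.scores.matrix.astype(np.float32), grid)


def _load_cohort(config: CohortConfig, out: Path) -> Cohort:
    cov_path = out / "covariates.csv"
    if not cov_path.exists():
        raise StageError(f"missing covariates table: {cov_path}")
    covs = pd.read_csv(cov_path)
    items = pd.read_csv(out / "items.csv").set_index("id")
    subjects = []
    for _, r in covs.iterrows():
        sid = r["id"]
        (hemi, strio_lat, s_sc, m_sc), grid = io.read_aligned(
            _maps_dir(out) / f"{sid}_hemisphere.nii.gz",
            _maps_dir(out) / f"{sid}_striosome_latent.nii.gz",
            _maps_dir(out) / f"{sid}_score_striosome.nii.gz",
            _maps_dir(out) / f"{sid}_score_matrix.nii.gz",
        )
        hemi = hemi.astype(np.int8)
        strio = strio_lat.astype(bool)
        bias = np.zeros(grid.dims)
        field = LatentCompartmentField(grid, hemi, strio, bias, (0, 0))
        record = SubjectRecord(
            id=sid, group=r["group"], age=float(r["age"]), sex=r["sex"],
            tiv_cm3=float(r["tiv_cm3"]),
            tsmv_left_cm3=float(r["tsmv_left_cm3"]),
            tsmv_right_cm3=float(r["tsmv_right_cm3"]),
            sbr_left=float(r["sbr_left"]), sbr_right=float(r["sbr_right"]),
            moca=int(r["moca"]),
            items={c: int(items.loc[sid, c]) for c in ALL_ITEMS},
            duration_years=float(r["duration_years"]),
        )
        scores = ScoreMapPair(grid, s_sc.astype(float), m_sc.astype(float))
        subjects.append(SyntheticSubject(record, field, scores))
    return Cohort(config=config, subjects=subjects)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the selected stages; returns the report directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort: Cohort | None = None
    metrics_df: pd.DataFrame | None = None

    # orchestration preflight: resuming stages need their inputs on disk
    first = config.stages[0] if config.stages else "simulate"
    if first in ("parcellate", "metrics") and not (out / "covariates.csv").exists():
        raise StageError(f"stage {first!r} needs covariates.csv in {out}")
    if first == "analyze" and not (out / "metrics.csv").exists():
        raise StageError(f"stage 'analyze' needs metrics.csv in {out}")

    counts: dict[str, int] = {}
    for stage in config.stages:
        try:
            if stage == "simulate":
                cohort = generate_cohort(config.cohort)
                _write_cohort(cohort, out, config.write_maps)
                counts["subjects"] = len(cohort.subjects)
            elif stage == "parcellate":
                if cohort is None:
                    cohort = _load_cohort(config.cohort, out)
                ldir = out / "labels"
                ldir.mkdir(exist_ok=True)
                nvox = 0
                for s in cohort.subjects:
                    bias = parcellation.compute_bias(s.scores, s.field.mask)
                    labels = parcellation.label_compartments(bias, config.parcellation)
                    io.write_volume(ldir / f"{s.record.id}_labels.nii.gz",
                                    labels.labels, s.field.grid)
                    nvox += int(s.field.mask.sum())
                counts["mask_voxels"] = nvox
            elif stage == "metrics":
                if cohort is None:
                    cohort = _load_cohort(config.cohort, out)
                metrics_df = metrics_mod.cohort_metrics(cohort, config.parcellation)
                metrics_df.to_csv(out / "metrics.csv", index=False, float_format=_FMT)
                counts["metric_rows"] = len(metrics_df)
            elif stage == "analyze":
                if metrics_df is None:
                    metrics_df = pd.read_csv(out / "metrics.csv")
                items_df = (pd.read_csv(out / "items.csv")
                            if (out / "items.csv").exists() else None)
                tables = analyze_cohort(
                    metrics_df, items_df, age_match=config.age_match,
                    drop_item9_overlap=config.drop_item9_overlap,
                    seed=config.seed)
                if (out / "covariates.csv").exists():
                    tables["demographics"] = demographics_table(
                        pd.read_csv(out / "covariates.csv"))
                for key, tab in tables.items():
                    tab.to_csv(out / f"{key}.csv", index=False, float_format=_FMT)
                counts["analysis_tables"] = len(tables)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate failing stage
            raise StageError(f"stage {stage!r} failed: {exc}") from exc

    io.ProvenanceRecord.create(config.cohort, config.seed, counts).write(
        out / "provenance.json")
    with open(out / "runlog.txt", "w") as fh:
        fh.write(f"seed={config.seed}\nstages={','.join(config.stages)}\n")
        for k, v in counts.items():
            fh.write(f"{k}={v}\n")
    return out
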