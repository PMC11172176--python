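"""End-to-end orchestration: quantify -> metrics -> associate -> survive.

``run_pipeline`` ties the stages together on file inputs (cells.csv,
regions.geojson, clinical.csv, survival.csv), writes each stage's outputs
into the output directory and records a manifest (config hash, seed, row
counts in/out per stage, exclusions) so every number in the report is
traceable to a stage output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from . import metrics as tmetrics
from . import stats as tstats
from . import survival as tsurv
from .geometry import assign_cells, region_areas

ASSOCIATION_FEATURES = {
    # feature column -> (levels or None for binary bool, ordered?)
    "grade": ([1, 2, 3], True),
    "ln_met": (None, False),
    "er": (None, False),
    "her2": (None, False),
    "necrosis": (None, False),
    "lvi": (None, False),
}


@dataclass
class PipelineConfig:
    cells_path: str | None = None
    regions_path: str | None = None
    clinical_path: str | None = None
    survival_path: str | None = None
    out_dir: str = "results"
    band_width_um: float = 50.0
    roi_area_mm2: float = 1.96
    area_weighted: bool = False
    per_roi_mean: bool = False
    p_remove: float = 0.10
    ties: str = "breslow"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.band_width_um <= 0:
            raise ValueError("band_width must be > 0")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def validate_inputs(
    cells: pd.DataFrame | None = None,
    geometries: list | None = None,
    clinical: pd.DataFrame | None = None,
    survival: pd.DataFrame | None = None,
) -> dict:
    """Schema and geometry sanity checks; machine-readable pass/fail."""
    checks = {}
    if cells is not None:
        for col in tio.CELLS_COLUMNS:
            checks[f"cells.has_{col}"] = col in cells.columns
        if {"x_um", "y_um"} <= set(cells.columns):
            checks["cells.finite_coordinates"] = bool(
                np.isfinite(cells[["x_um", "y_um"]].to_numpy()).all()
            )
        if "marker" in cells.columns:
            checks["cells.known_markers"] = bool(
                cells["marker"].isin(["CD163", "CD206"]).all()
            )
    if geometries is not None:
        checks["regions.valid_polygons"] = all(
            g.roi_polygon.is_valid and (g.tumor.is_empty or g.tumor.is_valid)
            for g in geometries
        )
        checks["regions.tumor_inside_roi"] = all(
            g.tumor.is_empty
            or g.tumor.intersection(g.roi_polygon).area >= 0.99 * g.tumor.area
            for g in geometries
        )
    if clinical is not None:
        checks["clinical.has_case_id"] = "case_id" in clinical.columns
        checks["clinical.has_stil"] = "stil_percent" in clinical.columns
    if survival is not None:
        for col in ("case_id", "dfs_months", "dfs_event", "os_months", "os_event"):
            checks[f"survival.has_{col}"] = col in survival.columns
        if {"dfs_months", "os_months"} <= set(survival.columns):
            checks["survival.positive_times"] = bool(
                (survival[["dfs_months", "os_months"]] > 0).all().all()
            )
    checks["all_passed"] = all(checks.values())
    return checks


def quantify(cells: pd.DataFrame, geometries: list) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign every detection to a compartment; tabulate ROI areas.

    Degenerate ROIs (no tumor nest) are excluded from stromal metrics with
    a logged warning; their cells get no compartment.
    """
    assigned, area_rows = [], []
    for geom in geometries:
        roi_cells = cells[
            (cells["case_id"] == geom.case_id) & (cells["roi_id"] == geom.roi_id)
        ]
        if geom.is_degenerate:
            warnings.warn(
                f"ROI {geom.case_id}/{geom.roi_id} has no tumor nest: excluded",
                stacklevel=2,
            )
            area_rows.append(
                {
                    "case_id": geom.case_id,
                    "roi_id": geom.roi_id,
                    "tumor_area_mm2": 0.0,
                    "stromal_area_mm2": 0.0,
                }
            )
            continue
        assigned.append(assign_cells(roi_cells, geom))
        t_area, s_area = region_areas(geom)
        area_rows.append(
            {
                "case_id": geom.case_id,
                "roi_id": geom.roi_id,
                "tumor_area_mm2": t_area,
                "stromal_area_mm2": s_area,
            }
        )
    out = (
        pd.concat(assigned, ignore_index=True)
        if assigned
        else cells.iloc[0:0].assign(compartment=None, distance_to_tumor=np.nan)
    )
    return out, pd.DataFrame(area_rows)


def associate(metrics_df: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate every high/low flag against the clinical features.

    One row per (feature, stratifier) with the chosen test, its statistic
    and raw two-sided p.
    """
    merged = clinical.set_index("case_id").join(metrics_df, how="inner")
    rows = []
    flag_cols = [c for c in metrics_df.columns if c.endswith("_high")]
    for feature, (levels, ordered) in ASSOCIATION_FEATURES.items():
        if feature not in merged.columns:
            continue
        for flag in flag_cols:
            sub = merged[[feature, flag]].dropna()
            if levels is None:
                lv = [False, True]
            else:
                lv = levels
            table = [
                [
                    int(((sub[feature] == v) & (sub[flag] == h)).sum())
                    for h in (False, True)
                ]
                for v in lv
            ]
            t = np.asarray(table)
            if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
                continue
            res = tstats.run_contingency(t, row_ordered=ordered)
            rows.append(
                {
                    "feature": feature,
                    "stratifier": flag,
                    "table": json.dumps(table),
                    "test": res.test,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p": res.p,
                }
            )
    return pd.DataFrame(rows)


def survive(
    metrics_df: pd.DataFrame,
    survival: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    p_remove: float = 0.10,
    ties: str = "breslow",
) -> dict:
    """KM + log-rank per stratifier and the backward-Wald Cox models."""
    merged = survival.set_index("case_id").join(metrics_df, how="inner")
    out: dict = {"logrank": [], "cox": {}}
    strat_cols = [c for c in metrics_df.columns if c.endswith("_high")] + [
        c for c in metrics_df.columns if c.startswith("group_")
    ]
    for endpoint in ("dfs", "os"):
        t = merged[f"{endpoint}_months"].to_numpy(float)
        e = merged[f"{endpoint}_event"].to_numpy(int)
        for col in strat_cols:
            ok = merged[col].notna().to_numpy()
            groups = merged[col][ok].astype(str).to_numpy()
            if len(np.unique(groups)) < 2 or e[ok].sum() == 0:
                continue
            res = tsurv.logrank(t[ok], e[ok], groups)
            out["logrank"].append(
                {
                    "endpoint": endpoint,
                    "stratifier": col,
                    "chi_square": res.statistic,
                    "df": res.df,
                    "p": res.p,
                }
            )
        if clinical is not None:
            x, names = _cox_design(merged, clinical)
            try:
                fit = tsurv.backward_stepwise_wald(
                    x, t, e, names, p_remove=p_remove, ties=ties
                )
                out["cox"][endpoint] = {
                    "final": fit.summary(),
                    "trace": fit.elimination_trace,
                }
            except (tsurv.CoxConvergenceError, ValueError) as err:
                out["cox"][endpoint] = {"error": str(err)}
    out["logrank"] = pd.DataFrame(out["logrank"])
    return out


def _cox_design(merged: pd.DataFrame, clinical: pd.DataFrame):
    """Initial-step design: age and size continuous; grade/pT/pN ordinal;
    markers as their median-split flags."""
    clin = clinical.set_index("case_id").reindex(merged.index)
    cols = {}
    for c in ("age", "size_cm", "grade", "pt_stage", "pn_stage"):
        if c in clin.columns:
            cols[c] = clin[c].astype(float)
    for c in ("er", "her2"):
        if c in clin.columns:
            cols[c] = clin[c].astype(float)
    for c in merged.columns:
        if c.endswith("_high") and merged[c].notna().all():
            cols[c] = merged[c].astype(float)
    x = pd.DataFrame(cols).dropna()
    keep = [c for c in x.columns if x[c].nunique() > 1]
    return x[keep].to_numpy(float), keep


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute quantify -> metrics -> associate -> survive on file inputs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cells = tio.read_cells(config.cells_path)
    geometries = tio.read_regions(config.regions_path, band_width=config.band_width_um)
    clinical = pd.read_csv(config.clinical_path) if config.clinical_path else None
    survival = pd.read_csv(config.survival_path) if config.survival_path else None

    checks = validate_inputs(cells, geometries, clinical, survival)
    if not checks["all_passed"]:
        failed = [k for k, v in checks.items() if not v and k != "all_passed"]
        raise ValueError(f"input validation failed: {failed}")

    geom_cases = {g.case_id for g in geometries}
    cell_cases = set(cells["case_id"])
    if not cell_cases <= geom_cases:
        raise ValueError(
            f"case ids in cells but not regions: {sorted(cell_cases - geom_cases)[:5]}"
        )

    manifest = {
        "config": config.as_dict(),
        "config_hash": tio.config_hash(config.as_dict()),
        "seed": config.seed,
        "counts": {"cells_in": len(cells), "rois": len(geometries)},
    }

    assigned, areas = quantify(cells, geometries)
    comp_counts = assigned["compartment"].value_counts().to_dict()
    manifest["counts"]["compartments"] = comp_counts
    assigned.to_csv(out_dir / "cells_assigned.csv", index=False)
    areas.to_csv(out_dir / "areas.csv", index=False)

    case_metrics = tmetrics.compute_case_metrics(
        assigned,
        areas,
        band_width=config.band_width_um,
        area_weighted=config.area_weighted,
        per_roi_mean=config.per_roi_mean,
    )
    case_metrics, cutoffs = tmetrics.stratify_cohort(case_metrics, clinical)
    case_metrics.to_csv(out_dir / "case_metrics.csv")
    (out_dir / "cutoffs.json").write_text(json.dumps(cutoffs, indent=2))
    manifest["counts"]["cases"] = len(case_metrics)

    results = {"case_metrics": case_metrics, "cutoffs": cutoffs, "manifest": manifest}
    if clinical is not None:
        assoc = associate(case_metrics, clinical)
        assoc.to_csv(out_dir / "associations.csv", index=False)
        results["associations"] = assoc
    if survival is not None:
        missing = set(case_metrics.index) - set(survival["case_id"])
        if missing:
            warnings.warn(
                f"{len(missing)} cases lack survival rows and are excluded "
                "from survival analysis",
                stacklevel=2,
            )
            manifest["counts"]["cases_without_followup"] = len(missing)
        surv_out = survive(
            case_metrics, survival, clinical,
            p_remove=config.p_remove, ties=config.ties,
        )
        surv_out["logrank"].to_csv(out_dir / "survival_tests.csv", index=False)
        (out_dir / "cox_model.json").write_text(
            json.dumps(surv_out["cox"], indent=2, default=str)
        )
        results["survival"] = surv_out
    tio.write_manifest(manifest, out_dir / "manifest.json")
    return results
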