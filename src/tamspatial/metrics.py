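"""Case-level TAM variables: densities, mean distances, median cutoffs.

From compartment-assigned cells this module derives the per-case quantities
the analysis stratifies on: marker density per compartment (sCD163, tCD163,
sCD206, tCD206 in cells/mm^2), mean stromal-cell distance to the tumor nest,
cohort-median high/low dichotomization of each, the joint stromal x tumoral
four-group label per marker, and density-to-sTIL ratio scores.

Aggregation conventions (configurable):

* density per compartment = unweighted mean of per-ROI densities over the
  ROIs where the compartment exists (``area_weighted=True`` switches to the
  area-weighted pooled count/area ratio);
* mean distance = cell-weighted pooling over all stromal cells of the marker
  across the case's ROIs (``per_roi_mean=True`` averages per-ROI means
  instead);
* high means strictly greater than the cohort median, so ties at the median
  are low.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

MARKERS = ("CD163", "CD206")
DENSITY_VARS = ("sCD163", "tCD163", "sCD206", "tCD206")
DISTANCE_VARS = ("dist_sCD163", "dist_sCD206")
RATIO_VARS = (
    "ratio_sCD163_sTIL",
    "ratio_tCD163_sTIL",
    "ratio_sCD206_sTIL",
    "ratio_tCD206_sTIL",
)

FOUR_GROUP_LABELS = ("sLO-tLO", "sLO-tHI", "sHI-tLO", "sHI-tHI")


def roi_density(count: float, area_mm2: float) -> float:
    """Cells per mm^2; NaN (missing) when the compartment has zero area."""
    if count < 0 or area_mm2 < 0:
        raise ValueError("count and area must be non-negative")
    if area_mm2 == 0:
        warnings.warn("zero compartment area: density undefined", stacklevel=2)
        return float("nan")
    return count / area_mm2


def aggregate_case(
    roi_densities: dict[str, list[float]],
    distances: dict[str, np.ndarray],
    area_weighted: bool = False,
    roi_areas: dict[str, list[float]] | None = None,
    per_roi_mean: bool = False,
) -> dict[str, float]:
    """Collapse per-ROI values to one row of case-level variables.

    ``roi_densities`` maps each density variable to the per-ROI density list
    (NaN where the compartment was degenerate); ``distances`` maps each
    distance variable to the pooled stromal-cell distances.
    """
    out: dict[str, float] = {}
    for var, vals in roi_densities.items():
        vals = np.asarray(vals, dtype=float)
        ok = ~np.isnan(vals)
        if not ok.any():
            out[var] = float("nan")
        elif area_weighted:
            if roi_areas is None:
                raise ValueError("area_weighted aggregation needs roi_areas")
            areas = np.asarray(roi_areas[var], dtype=float)[ok]
            out[var] = float(np.sum(vals[ok] * areas) / np.sum(areas))
        else:
            out[var] = float(vals[ok].mean())
    for var, d in distances.items():
        d = np.asarray(d, dtype=float)
        if per_roi_mean:
            # d is then a list of per-ROI means
            d = d[~np.isnan(d)]
        out[var] = float(d.mean()) if d.size else float("nan")
    return out


def dichotomize(values: pd.Series) -> tuple[float, pd.Series]:
    """Median cutoff and high/low flags for one cohort variable.

    Cutoff is the sample median of non-missing values (midpoint convention
    for even n); ``high`` is True iff value > cutoff, so ties at the median
    are low.  Missing values stay missing.

    Returns ``(cutoff, flags)`` where flags is a nullable boolean Series.
    """
    v = pd.Series(values, dtype=float)
    nonmiss = v.dropna()
    if len(nonmiss) < 2:
        raise ValueError("need >= 2 non-missing values to dichotomize")
    cutoff = float(nonmiss.median())
    if nonmiss.nunique() == 1:
        warnings.warn(
            "all values identical: whole cohort is in the low group",
            stacklevel=2,
        )
    flags = pd.Series(pd.NA, index=v.index, dtype="boolean")
    flags[v.notna()] = v[v.notna()] > cutoff
    return cutoff, flags


def four_group(s_high, t_high):
    """Joint stromal x tumoral label, e.g. (low, high) -> 'sLO-tHI'."""
    if pd.isna(s_high) or pd.isna(t_high):
        return None
    return f"s{'HI' if s_high else 'LO'}-t{'HI' if t_high else 'LO'}"


def tam_til_ratio(density: float, stil_percent: float) -> float:
    """Density-to-sTIL ratio score; missing when sTIL is 0."""
    if pd.isna(density) or pd.isna(stil_percent):
        return float("nan")
    if density < 0 or stil_percent < 0:
        raise ValueError("density and sTIL must be non-negative")
    if stil_percent == 0:
        warnings.warn("sTIL = 0: ratio undefined, case excluded", stacklevel=2)
        return float("nan")
    return density / stil_percent


def compute_case_metrics(
    cells: pd.DataFrame,
    areas: pd.DataFrame,
    band_width: float = 50.0,
    area_weighted: bool = False,
    per_roi_mean: bool = False,
) -> pd.DataFrame:
    """Per-case density and distance variables from assigned cells.

    Parameters
    ----------
    cells : DataFrame with case_id, roi_id, marker, compartment,
        distance_to_tumor (output of the geometry stage).
    areas : DataFrame with case_id, roi_id, tumor_area_mm2, stromal_area_mm2
        (one row per ROI; zero area marks a degenerate compartment).
    """
    rows = []
    for case_id, case_areas in areas.groupby("case_id", sort=True):
        case_cells = cells[cells["case_id"] == case_id]
        dens: dict[str, list[float]] = {v: [] for v in DENSITY_VARS}
        ar: dict[str, list[float]] = {v: [] for v in DENSITY_VARS}
        dists = {v: [] for v in DISTANCE_VARS}
        for _, roi in case_areas.iterrows():
            roi_cells = case_cells[case_cells["roi_id"] == roi["roi_id"]]
            for marker in MARKERS:
                mc = roi_cells[roi_cells["marker"] == marker]
                for comp, prefix, area_col in (
                    ("stroma", "s", "stromal_area_mm2"),
                    ("tumor", "t", "tumor_area_mm2"),
                ):
                    area = float(roi[area_col])
                    n = int((mc["compartment"] == comp).sum())
                    var = f"{prefix}{marker}"
                    if area > 0:
                        dens[var].append(roi_density(n, area))
                    else:
                        dens[var].append(float("nan"))
                    ar[var].append(area)
                svar = f"dist_s{marker}"
                stromal = mc[mc["compartment"] == "stroma"]
                if per_roi_mean:
                    dists[svar].append(
                        float(stromal["distance_to_tumor"].mean())
                        if len(stromal)
                        else float("nan")
                    )
                else:
                    dists[svar].extend(stromal["distance_to_tumor"].tolist())
        row = aggregate_case(
            dens,
            {k: np.asarray(v, dtype=float) for k, v in dists.items()},
            area_weighted=area_weighted,
            roi_areas=ar,
            per_roi_mean=per_roi_mean,
        )
        row["case_id"] = case_id
        rows.append(row)
    return pd.DataFrame(rows).set_index("case_id")


def stratify_cohort(
    metrics: pd.DataFrame, clinical: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Median-dichotomize every variable and build derived stratifiers.

    Adds ``<var>_high`` flags for densities and distances, the per-marker
    four-group labels, and (when ``clinical`` with an ``stil_percent`` column
    is given) the four TAM/sTIL ratio scores with their own flags.

    Returns the augmented table and a cutoffs record
    ``{variable: {"cutoff": value, "n": count}}``.
    """
    out = metrics.copy()
    cutoffs: dict[str, dict] = {}
    if clinical is not None and "stil_percent" in clinical.columns:
        stil = clinical.set_index("case_id")["stil_percent"].reindex(out.index)
        for var in DENSITY_VARS:
            out[f"ratio_{var}_sTIL"] = [
                tam_til_ratio(d, s) for d, s in zip(out[var], stil)
            ]
    for var in list(DENSITY_VARS) + list(DISTANCE_VARS) + [
        c for c in out.columns if c.startswith("ratio_")
    ]:
        if var not in out.columns:
            continue
        cutoff, flags = dichotomize(out[var])
        out[f"{var}_high"] = flags
        cutoffs[var] = {"cutoff": cutoff, "n": int(out[var].notna().sum())}
    for marker in MARKERS:
        out[f"group_{marker}"] = [
            four_group(s, t)
            for s, t in zip(out[f"s{marker}_high"], out[f"t{marker}_high"])
        ]
    return out, cutoffs
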