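"""Reading and writing the pipeline's file formats.

Cells, clinical and survival tables travel as CSV; ROI and tumor-nest
geometries travel as GeoJSON FeatureCollections in micrometre coordinates,
features tagged with ``role`` (roi | tumor), ``case_id`` and ``roi_id``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from .geometry import RegionGeometry, _as_multipolygon

CELLS_COLUMNS = ["case_id", "roi_id", "marker", "x_um", "y_um"]


def write_cells(cells: pd.DataFrame, path) -> None:
    cols = [c for c in cells.columns if c in CELLS_COLUMNS] + [
        c for c in cells.columns if c not in CELLS_COLUMNS
    ]
    cells[cols].to_csv(path, index=False)


def read_cells(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CELLS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cells table missing columns {missing}")
    return df


def write_regions(geometries: list[RegionGeometry], path) -> None:
    features = []
    for g in geometries:
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "role": "roi",
                    "case_id": g.case_id,
                    "roi_id": g.roi_id,
                    "band_width_um": g.band_width,
                },
                "geometry": mapping(g.roi_polygon),
            }
        )
        if not g.tumor.is_empty:
            features.append(
                {
                    "type": "Feature",
                    "properties": {
                        "role": "tumor",
                        "case_id": g.case_id,
                        "roi_id": g.roi_id,
                    },
                    "geometry": mapping(g.tumor),
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_regions(path, band_width: float | None = None) -> list[RegionGeometry]:
    with open(path) as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    rois, tumors, bands = {}, {}, {}
    for i, feat in enumerate(fc.get("features", [])):
        props = feat.get("properties") or {}
        role = props.get("role")
        key = (props.get("case_id"), props.get("roi_id"))
        if None in key or role not in ("roi", "tumor"):
            raise ValueError(f"{path}: feature {i} lacks role/case_id/roi_id")
        geom = shape(feat["geometry"])
        if role == "roi":
            rois[key] = geom
            bands[key] = props.get("band_width_um")
        else:
            tumors[key] = _as_multipolygon(geom)
    out = []
    for key, roi in sorted(rois.items()):
        bw = band_width if band_width is not None else (bands.get(key) or 50.0)
        out.append(
            RegionGeometry(
                case_id=key[0],
                roi_id=key[1],
                roi_polygon=roi,
                tumor=tumors.get(key, _as_multipolygon(None)),
                band_width=float(bw),
            )
        )
    return out


def write_config(config: dict, path) -> None:
    """Flat key=value text file, sorted for stable hashing."""
    with open(path, "w") as fh:
        for k in sorted(config):
            fh.write(f"{k}={config[k]}\n")


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
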