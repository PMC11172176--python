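#!/usr/bin/env python
"""Step 2 — assign detected cells to tumor / peritumoral-stroma compartments.

Reads the cohort written by 01_simulate.py, validates it, assigns every cell
to a compartment with its distance to the nearest tumor nest, and writes the
per-ROI compartment areas.
"""

from pathlib import Path

import pandas as pd

from tamspatial import io as tio
from tamspatial.pipeline import quantify, validate_inputs

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = ROOT / "results" / "cohort"
    cells = tio.read_cells(cohort / "cells.csv")
    geoms = tio.read_regions(cohort / "regions.geojson")

    checks = validate_inputs(cells, geoms,
                             pd.read_csv(cohort / "clinical.csv"),
                             pd.read_csv(cohort / "survival.csv"))
    assert checks["all_passed"], checks

    assigned, areas = quantify(cells, geoms)
    assigned.to_csv(cohort / "cells_assigned.csv", index=False)
    areas.to_csv(cohort / "areas.csv", index=False)

    counts = assigned["compartment"].value_counts()
    print(f"{len(assigned)} cells over {len(areas)} ROIs")
    print(counts.to_string())


if __name__ == "__main__":
    main()
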