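#!/usr/bin/env python
"""Step 3 — case-level TAM metrics and median stratification.

Aggregates ROI densities and tumor distances to one row per case, then
dichotomizes every density at the cohort median and forms the four-group
(stromal x tumoral) and TAM/sTIL ratio scores.
"""

import json
from pathlib import Path

import pandas as pd

from tamspatial.metrics import compute_case_metrics, stratify_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = ROOT / "results" / "cohort"
    cm = compute_case_metrics(
        pd.read_csv(cohort / "cells_assigned.csv"), pd.read_csv(cohort / "areas.csv")
    )
    cm, cutoffs = stratify_cohort(cm, pd.read_csv(cohort / "clinical.csv"))
    cm.to_csv(cohort / "case_metrics.csv")
    (cohort / "cutoffs.json").write_text(json.dumps(cutoffs, indent=2))

    med = cm[["sCD163", "tCD163", "sCD206", "tCD206"]].median().round(1)
    print("measured median densities (cells/mm^2):")
    print(med.to_string())
    print("\nmedian cutoffs:", json.dumps(cutoffs, indent=2))


if __name__ == "__main__":
    main()
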