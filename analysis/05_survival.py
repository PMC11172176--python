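#!/usr/bin/env python
"""Step 5 — survival analysis on the synthetic cohort.

Log-rank stratification of DFS/OS by each median-split flag and four-group
score, followed by Cox models with backward Wald elimination (p_remove=0.10).
"""

import json
from pathlib import Path

import pandas as pd

from tamspatial.pipeline import survive

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = ROOT / "results" / "cohort"
    cm = pd.read_csv(cohort / "case_metrics.csv", index_col="case_id")
    res = survive(
        cm,
        pd.read_csv(cohort / "survival.csv"),
        pd.read_csv(cohort / "clinical.csv"),
    )
    out = ROOT / "results"
    res["logrank"].to_csv(out / "survival_tests.csv", index=False)
    (out / "cox_models.json").write_text(
        json.dumps(res["cox"], indent=2, default=str)
    )

    lr = res["logrank"].sort_values("p")
    print("log-rank tests (most significant first):")
    print(lr.head(8).to_string(index=False))
    for endpoint, model in res["cox"].items():
        print(f"\nCox model, {endpoint} (after backward Wald selection):")
        if "error" in model:
            print(f"  not fit: {model['error']}")
            continue
        for name, row in model["final"].items():
            print(
                f"  {name:28s} HR {row['hr']:6.3f} "
                f"({row['ci_lower']:.3f}-{row['ci_upper']:.3f})  p={row['p']:.4f}"
            )


if __name__ == "__main__":
    main()
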