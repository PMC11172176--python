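"""Association statistics for clinico-pathological cross-tabulations.

The battery used throughout the cohort tables: uncorrected Pearson
chi-square for unordered contingency tables, the linear-by-linear
(Mantel–Haenszel trend) chi-square for ordered categories such as tumor
grade, Fisher's exact test when expected counts are small, Spearman
rank correlation for continuous marker densities, Mann–Whitney U for age
and tumor size, and the Wilcoxon signed-rank test for paired
tumor-vs-stroma density comparisons.

Test choice follows a deterministic rule (``choose_test``): ordered rows
with at least three levels get the trend statistic; a 2x2 table with any
expected count below 5 gets Fisher's exact test; everything else gets the
uncorrected Pearson chi-square.  No continuity correction and no multiple-
testing adjustment are applied anywhere; every p-value is reported raw with
the test that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class StatResult:
    """One test outcome: statistic, degrees of freedom, two-sided p."""

    test: str
    statistic: float
    p: float
    df: int | None = None
    effect: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p out of [0,1]: {self.p}")


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    return t


def expected_counts(table) -> np.ndarray:
    t = _as_table(table)
    n = t.sum()
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / n


def pearson_chi2(table) -> StatResult:
    """Pearson chi-square without continuity correction.

    X^2 = sum (O-E)^2/E, df = (r-1)(c-1), upper-tail p.
    """
    t = _as_table(table)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError(
            "zero margin: collapse the empty level or use fisher_exact"
        )
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    return StatResult("pearson_chi2", float(chi2), float(p), int(df))


def trend_chi2(table, scores=None) -> StatResult:
    """Linear-by-linear association (Mantel–Haenszel trend) chi-square.

    For an ordered r x 2 table, M^2 = (n-1) r^2 with r the Pearson
    correlation between the integer row scores and the column indicator over
    the n subjects; df = 1.  This is the statistic SPSS prints as
    "Linear-by-Linear Association".
    """
    t = _as_table(table)
    if t.shape[0] < 3:
        raise ValueError("trend test needs >= 3 ordered row levels")
    if scores is None:
        scores = np.arange(1, t.shape[0] + 1, dtype=float)
    scores = np.asarray(scores, dtype=float)
    col_scores = np.arange(t.shape[1], dtype=float)
    n = t.sum()
    # correlation over the n subjects, computed from the table weights
    w = t / n
    mx = (scores[:, None] * w).sum()
    my = (col_scores[None, :] * w).sum()
    sxx = ((scores[:, None] - mx) ** 2 * w).sum()
    syy = ((col_scores[None, :] - my) ** 2 * w).sum()
    sxy = ((scores[:, None] - mx) * (col_scores[None, :] - my) * w).sum()
    if sxx <= 0 or syy <= 0:
        raise ValueError("degenerate table: zero variance in rows or columns")
    r = sxy / np.sqrt(sxx * syy)
    m2 = (n - 1) * r**2
    p = float(sps.chi2.sf(m2, df=1))
    return StatResult("trend_chi2", float(m2), p, 1, effect={"r": float(r)})


def fisher_exact(table) -> StatResult:
    """Two-sided Fisher exact test on a 2x2 table (probability-mass rule)."""
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact requires a 2x2 table")
    odds, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    return StatResult(
        "fisher_exact", float(odds), float(p), effect={"odds_ratio": float(odds)}
    )


def choose_test(table, row_ordered: bool = False) -> str:
    """Deterministic test-choice rule for a contingency table.

    Ordered rows with >= 3 levels -> trend_chi2; else a 2x2 with any
    expected count < 5 -> fisher_exact; else pearson_chi2.
    """
    t = _as_table(table)
    if row_ordered and t.shape[0] >= 3:
        return "trend_chi2"
    if t.shape == (2, 2) and expected_counts(t).min() < 5:
        return "fisher_exact"
    return "pearson_chi2"


_TESTS = {}


def run_contingency(table, row_ordered: bool = False) -> StatResult:
    """Apply ``choose_test`` and run the chosen test."""
    name = choose_test(table, row_ordered=row_ordered)
    return _TESTS[name](table)


def spearman_rho(x, y) -> StatResult:
    """Spearman rank correlation (mid-ranks for ties), t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    rs, p = sps.spearmanr(x, y)
    return StatResult("spearman", float(rs), float(p), effect={"rs": float(rs)})


def mann_whitney(a, b) -> StatResult:
    """Mann–Whitney U, two-sided.

    Exact null distribution for small untied samples; tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return StatResult("mann_whitney", float(u), float(p))


def wilcoxon_signed_rank(a, b) -> StatResult:
    """Wilcoxon signed-rank on paired samples; zero differences dropped.

    Exact for small untied samples, tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b
    if np.all(d == 0):
        raise ValueError("all paired differences are zero")
    w, p = sps.wilcoxon(
        a, b, zero_method="wilcox", correction=False, method="auto"
    )
    return StatResult("wilcoxon_signed_rank", float(w), float(p))


def mcnemar(table) -> StatResult:
    """McNemar exact test on a paired 2x2 classification table.

    Used for paired high/low comparisons of the same cases under two
    stratifiers (e.g. stromal vs tumoral status of one marker).  Exact
    binomial on the discordant pairs.
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError("mcnemar requires a 2x2 paired table")
    b, c = t[0, 1], t[1, 0]
    n = int(b + c)
    if n == 0:
        return StatResult("mcnemar_exact", 0.0, 1.0)
    res = sps.binomtest(int(min(b, c)), n, 0.5, alternative="two-sided")
    return StatResult("mcnemar_exact", float(min(b, c)), float(res.pvalue))


_TESTS.update(
    {
        "pearson_chi2": pearson_chi2,
        "trend_chi2": trend_chi2,
        "fisher_exact": fisher_exact,
    }
)
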