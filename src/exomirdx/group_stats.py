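"""Group summaries, differential-expression tests, and demographics tests.

Confidence intervals of group means are t-based: mean ± t_{(1+level)/2, n−1}
· sd/√n (sample SD, ddof=1). Two-group comparisons use Student's two-tailed
t-test by default (pooled variance), with Welch as an option. Stage-
stratified tests compare each PDAC stage bucket (early = stages I–II,
mid = III, late = IV) against the full control group. Demographic group
association uses Pearson's chi-squared on group × category tables; age is
binned into decades first, and a plain t-test on age is also available.

No multiple-testing correction is applied by default (raw per-miRNA
p-values are reported); Benjamini–Hochberg adjustment is available via
:func:`adjust_pvalues`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, UndefinedMetricError
from .preprocess import DeltaCqMatrix

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVELS = (0.001, 0.01, 0.05)
STAGE_BUCKET_ORDER = ("early", "mid", "late")


@lru_cache(maxsize=None)
def _t_quantile(level: float, df: int) -> float:
    return float(stats.t.ppf((1.0 + level) / 2.0, df=df))


def ci99_mean(values: Sequence[float], level: float = 0.99) -> tuple[float, float]:
    """Two-sided t-based confidence interval of the mean (default 99%)."""
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n < 2:
        raise InvalidParameterError("CI of the mean requires n >= 2")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    half = _t_quantile(level, n - 1) * sd / np.sqrt(n)
    return (mean - half, mean + half)


def significance_stars(p_value: float) -> tuple[float | None, str]:
    """Map a p-value to the strictest conventional threshold it beats.

    Returns ``(threshold, stars)`` with stars in {'***', '**', '*', 'ns'}.
    A pure function of the p-value and the 0.05/0.01/0.001 ladder.
    """
    for thr, stars in zip(SIGNIFICANCE_LEVELS, ("***", "**", "*")):
        if p_value < thr:
            return thr, stars
    return None, "ns"


@dataclass
class TestResult:
    comparison: str
    statistic: float
    p_value: float
    df: float | None = None
    mirna_id: str | None = None
    test: str = "t"

    @property
    def significant_at(self) -> float | None:
        return significance_stars(self.p_value)[0]

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)[1]


def two_group_ttest(
    x: Sequence[float],
    y: Sequence[float],
    variant: Literal["student", "welch"] = "student",
    comparison: str = "x_vs_y",
    mirna_id: str | None = None,
) -> TestResult:
    """Two-tailed two-sample t-test (pooled-variance Student's by default).

    Degenerate input where both groups are identical constants yields
    t = 0, p = 1 rather than NaN.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidParameterError("each group needs n >= 2 for a t-test")
    if variant not in ("student", "welch"):
        raise InvalidParameterError(f"unknown t-test variant: {variant}")
    if x.std(ddof=1) == 0.0 and y.std(ddof=1) == 0.0 and x.mean() == y.mean():
        dof = float(x.size + y.size - 2)
        return TestResult(comparison, 0.0, 1.0, dof, mirna_id)
    res = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    return TestResult(
        comparison, float(res.statistic), float(res.pvalue), float(res.df), mirna_id
    )


def group_summaries(
    matrix: DeltaCqMatrix,
    metadata: pd.DataFrame,
    level: float = 0.99,
) -> pd.DataFrame:
    """Per-miRNA summary (n, mean, sd, CI of the mean) for the control and
    PDAC groups and each PDAC stage bucket present in the metadata."""
    meta = metadata.set_index("sample_id").loc[matrix.samples]
    groups: dict[str, pd.Index] = {
        "control": meta.index[meta["group"] == "control"],
        "pdac": meta.index[meta["group"] == "pdac"],
    }
    for bucket in STAGE_BUCKET_ORDER:
        ids = meta.index[(meta["group"] == "pdac") & (meta["stage_bucket"] == bucket)]
        if len(ids):
            groups[bucket] = ids
    rows = []
    for gname, ids in groups.items():
        sub = matrix.values.loc[ids]
        for mid in matrix.retained_mirnas:
            vals = sub[mid].to_numpy()
            n = len(vals)
            mean = float(vals.mean()) if n else np.nan
            sd = float(vals.std(ddof=1)) if n >= 2 else np.nan
            lo, hi = ci99_mean(vals, level) if n >= 2 else (np.nan, np.nan)
            rows.append((mid, gname, n, mean, sd, lo, hi))
    return pd.DataFrame(
        rows, columns=["mirna_id", "group", "n", "mean", "sd", "ci_low", "ci_high"]
    )


def differential_tests(
    matrix: DeltaCqMatrix,
    metadata: pd.DataFrame,
    variant: Literal["student", "welch"] = "student",
) -> pd.DataFrame:
    """Control vs PDAC t-test for every retained miRNA."""
    meta = metadata.set_index("sample_id").loc[matrix.samples]
    ctrl = matrix.values.loc[meta.index[meta["group"] == "control"]]
    pdac = matrix.values.loc[meta.index[meta["group"] == "pdac"]]
    results = [
        two_group_ttest(
            ctrl[mid], pdac[mid], variant, comparison="control_vs_pdac", mirna_id=mid
        )
        for mid in matrix.retained_mirnas
    ]
    return _results_frame(results)


def stage_stratified_tests(
    matrix: DeltaCqMatrix,
    metadata: pd.DataFrame,
    variant: Literal["student", "welch"] = "student",
) -> pd.DataFrame:
    """Each PDAC stage bucket vs the full control group, per retained miRNA.

    Buckets with fewer than 2 samples are skipped with a warning (a t-test
    is undefined there).
    """
    meta = metadata.set_index("sample_id").loc[matrix.samples]
    ctrl_ids = meta.index[meta["group"] == "control"]
    results: list[TestResult] = []
    for bucket in STAGE_BUCKET_ORDER:
        ids = meta.index[(meta["group"] == "pdac") & (meta["stage_bucket"] == bucket)]
        if len(ids) < 2:
            logger.warning(
                "stage bucket %r has %d samples; skipped", bucket, len(ids)
            )
            continue
        for mid in matrix.retained_mirnas:
            results.append(
                two_group_ttest(
                    matrix.values.loc[ctrl_ids, mid],
                    matrix.values.loc[ids, mid],
                    variant,
                    comparison=f"control_vs_{bucket}",
                    mirna_id=mid,
                )
            )
    return _results_frame(results)


def chi_squared_demographics(
    metadata: pd.DataFrame,
    variable: Literal["sex", "ethnicity", "age"],
    age_bin_width: float = 10.0,
) -> TestResult:
    """Pearson chi-squared association between study group and a demographic.

    Age is binned into ``age_bin_width``-year bins before tabulation (a
    chi-squared test is undefined on a continuous variable). Categories or
    groups with zero totals are dropped with a warning.
    """
    if variable == "age":
        ages = metadata["age"].astype(float)
        lo = np.floor(ages.min() / age_bin_width) * age_bin_width
        hi = np.ceil(ages.max() / age_bin_width) * age_bin_width
        edges = np.arange(lo, hi + age_bin_width, age_bin_width)
        cat = pd.cut(ages, bins=edges, include_lowest=True)
    else:
        cat = metadata[variable]
    table = pd.crosstab(metadata["group"], cat)
    empty_cols = table.columns[(table.sum(axis=0) == 0)]
    if len(empty_cols):
        logger.warning("dropping empty categories: %s", list(empty_cols))
        table = table.drop(columns=empty_cols)
    table = table.loc[table.sum(axis=1) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise UndefinedMetricError(
            f"chi-squared on {variable!r} needs >= 2 groups and >= 2 categories"
        )
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return TestResult(
        comparison=f"group_vs_{variable}",
        statistic=float(chi2),
        p_value=float(p),
        df=float(dof),
        test="chi2",
    )


def age_ttest(
    metadata: pd.DataFrame, variant: Literal["student", "welch"] = "student"
) -> TestResult:
    """Two-group t-test on age, the continuous-variable companion to the
    chi-squared association test."""
    ctrl = metadata.loc[metadata["group"] == "control", "age"]
    pdac = metadata.loc[metadata["group"] == "pdac", "age"]
    return two_group_ttest(ctrl, pdac, variant, comparison="age_control_vs_pdac")


def adjust_pvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional; off by default in
    the pipeline, which reports raw per-miRNA p-values)."""
    return stats.false_discovery_control(np.asarray(list(p_values), dtype=float))


def _results_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": r.mirna_id,
                "comparison": r.comparison,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "df": r.df,
                "significant_at": r.significant_at,
                "stars": r.stars,
            }
            for r in results
        ]
    )
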