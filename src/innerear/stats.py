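"""Cohort statistics: normality, laterality, TIV correlation, sex ANCOVA.

The battery applied to per-(subject, side) morphometric tables:

* Kolmogorov-Smirnov normality with the Lilliefors correction (parameters
  estimated from the sample), p-values by seeded Monte Carlo;
* paired left-vs-right comparisons with a normality gate (paired t-test for
  normal differences, rank test otherwise) and Benjamini-Hochberg FDR
  correction across the measure family;
* Pearson correlation of measures (averaged over sides) with total
  intracranial volume (TIV);
* one-way ANCOVA for a sex effect with TIV as covariate (Type-II sums of
  squares).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "AncovaResult",
    "lilliefors_normality",
    "laterality_tests",
    "bh_fdr",
    "tiv_correlations",
    "gender_ancova",
    "summarize_cohort",
]


@dataclass
class TestResult:
    test: str
    statistic: float
    pvalue: float
    n: int
    p_adjusted: float | None = None
    measure: str | None = None
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        p = self.p_adjusted if self.p_adjusted is not None else self.pvalue
        return p < 0.05


@dataclass
class AncovaResult:
    F: float
    df_between: int
    df_residual: int
    pvalue: float
    adjusted_means: dict[str, float]

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F statistic must be non-negative")


def _lilliefors_stat(x: np.ndarray) -> float:
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = sps.norm.cdf(z)
    upper = np.arange(1, n + 1) / n - cdf
    lower = cdf - np.arange(0, n) / n
    return float(max(upper.max(), lower.max()))


@lru_cache(maxsize=64)
def _lilliefors_null(n: int, n_mc: int, seed: int) -> np.ndarray:
    """Monte-Carlo null distribution of the Lilliefors statistic (sorted)."""
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_mc, n))
    draws.sort(axis=1)
    z = (draws - draws.mean(axis=1, keepdims=True)) / draws.std(axis=1, ddof=1,
                                                                keepdims=True)
    cdf = sps.norm.cdf(z)
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    d = np.maximum((grid_hi - cdf).max(axis=1), (cdf - grid_lo).max(axis=1))
    return np.sort(d)


def lilliefors_normality(sample, n_mc: int = 10_000,
                         seed: int = 875_2025) -> TestResult:
    """KS test against a normal with estimated mean/SD (Lilliefors).

    The p-value is the Monte-Carlo exceedance probability under the null,
    from a cached, seeded null distribution (reproducible by construction).
    Requires n >= 4; constant samples raise.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 4:
        raise ValueError(f"need at least 4 observations, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    stat = _lilliefors_stat(x)
    null = _lilliefors_null(len(x), n_mc, seed)
    n_ge = len(null) - np.searchsorted(null, stat, side="left")
    p = (1.0 + n_ge) / (n_mc + 1.0)
    return TestResult(test="lilliefors", statistic=stat, pvalue=float(p),
                      n=len(x))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _paired_sides(cohort: pd.DataFrame, measure: str):
    wide = cohort.pivot_table(index="subject", columns="side", values=measure)
    wide = wide.dropna()
    return wide["L"].to_numpy(), wide["R"].to_numpy(), wide.index


def laterality_tests(cohort: pd.DataFrame, measures,
                     alpha: float = 0.05,
                     nonnormal_test: str = "mannwhitney") -> list[TestResult]:
    """Left-vs-right comparison per measure with BH-FDR across the family.

    Paired differences are gated through the Lilliefors normality test: a
    two-tailed paired t-test where normal, otherwise the Mann-Whitney U test
    on the two side samples (the historically used choice; pass
    ``nonnormal_test='wilcoxon'`` for the paired signed-rank alternative).
    Subjects missing a side are excluded per measure.
    """
    if nonnormal_test not in ("mannwhitney", "wilcoxon"):
        raise ValueError(f"unknown nonnormal_test {nonnormal_test!r}")
    results: list[TestResult] = []
    for m in measures:
        left, right, _ = _paired_sides(cohort, m)
        diffs = left - right
        n = len(diffs)
        if n < 4:
            raise ValueError(f"measure {m}: fewer than 4 complete pairs")
        if np.ptp(diffs) == 0:
            # exactly symmetric sides: no evidence of any difference
            results.append(TestResult(test="paired_t", statistic=0.0,
                                      pvalue=1.0, n=n, measure=m))
            continue
        normal = lilliefors_normality(diffs).pvalue >= alpha
        if normal:
            stat, p = sps.ttest_rel(left, right)
            results.append(TestResult(test="paired_t", statistic=float(stat),
                                      pvalue=float(p), n=n, measure=m))
        elif nonnormal_test == "mannwhitney":
            stat, p = sps.mannwhitneyu(left, right, alternative="two-sided")
            results.append(TestResult(test="mannwhitney",
                                      statistic=float(stat), pvalue=float(p),
                                      n=n, measure=m,
                                      extra={"normal": False}))
        else:
            stat, p = sps.wilcoxon(left, right)
            results.append(TestResult(test="wilcoxon", statistic=float(stat),
                                      pvalue=float(p), n=n, measure=m,
                                      extra={"normal": False}))
    adjusted = bh_fdr([r.pvalue for r in results])
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = float(p_adj)
    return results


def tiv_correlations(cohort: pd.DataFrame, measures) -> list[TestResult]:
    """Pearson correlation of each measure with TIV.

    Measures are averaged over the two sides within subject first (one value
    per subject), then correlated against the subject's TIV.
    """
    per_subject = cohort.groupby("subject").agg(
        {**{m: "mean" for m in measures}, "tiv_cm3": "first"})
    results = []
    for m in measures:
        x = per_subject["tiv_cm3"].to_numpy(dtype=float)
        y = per_subject[m].to_numpy(dtype=float)
        if len(x) < 3:
            raise ValueError("need at least 3 subjects for a correlation")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"zero variance in correlation inputs for {m}")
        r, p = sps.pearsonr(x, y)
        results.append(TestResult(test="pearson", statistic=float(r),
                                  pvalue=float(p), n=len(x), measure=m))
    return results


def gender_ancova(cohort: pd.DataFrame, measure: str) -> AncovaResult:
    """One-way ANCOVA: measure ~ sex + TIV (Type-II sums of squares).

    Side-averaged per-subject values; reports the F statistic for the sex
    term, its degrees of freedom, p-value, and TIV-adjusted group means
    (predictions at the grand-mean TIV).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    per_subject = cohort.groupby("subject").agg(
        {measure: "mean", "tiv_cm3": "first", "sex": "first"}).reset_index()
    groups = per_subject["sex"].unique()
    if len(groups) < 2:
        raise ValueError("ANCOVA needs two sex groups")
    df = per_subject.rename(columns={measure: "y", "tiv_cm3": "tiv"})
    if np.ptp(df["tiv"].to_numpy(dtype=float)) == 0:
        # degenerate covariate: reduces exactly to a one-way ANOVA
        model = smf.ols("y ~ C(sex)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        row = table.loc["C(sex)"]
        df_resid = int(model.df_resid)
    else:
        model = smf.ols("y ~ C(sex) + tiv", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        row = table.loc["C(sex)"]
        df_resid = int(model.df_resid)
    tiv_bar = float(df["tiv"].mean())
    adjusted = {}
    for g in groups:
        pred = df.assign(sex=g, tiv=tiv_bar)
        adjusted[str(g)] = float(model.predict(pred).iloc[0])
    return AncovaResult(
        F=float(row["F"]), df_between=int(row["df"]),
        df_residual=df_resid, pvalue=float(row["PR(>F)"]),
        adjusted_means=adjusted,
    )


def summarize_cohort(cohort: pd.DataFrame, measures=None,
                     decimals: int | None = None) -> pd.DataFrame:
    """Mean and sample SD (ddof=1) per measure over all (subject, side) rows."""
    if len(cohort) < 2:
        raise ValueError("need at least 2 rows to summarize")
    if measures is None:
        skip = {"subject", "side", "sex", "tiv_cm3"}
        measures = [c for c in cohort.columns
                    if c not in skip and pd.api.types.is_numeric_dtype(cohort[c])]
    rows = []
    for m in measures:
        vals = cohort[m].to_numpy(dtype=float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if decimals is not None:
            factor = 10.0 ** decimals
            mean = math.floor(abs(mean) * factor + 0.5) / factor * np.sign(mean)
            sd = math.floor(sd * factor + 0.5) / factor
        rows.append((m, mean, sd))
    return pd.DataFrame(rows, columns=["measure", "mean", "sd"])
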