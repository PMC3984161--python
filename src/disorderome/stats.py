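"""Two-tier statistical comparison protocol and descriptive summaries.

Per-protein measurements (disorder content, segment counts, MoRF counts)
are compared between two protein populations with a t-test when both groups
pass an Anderson-Darling normality check at alpha = 0.05, and with the
two-sided Wilcoxon rank-sum test otherwise.  Population-level measurements
(e.g. the fraction of fully disordered proteins) are compared by evaluating
the measure on ten random half-subsets of each population and testing the
two resulting 10-vectors the same way.  Medians with 25th/75th centiles are
always reported, since most of these measurements are not normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .config import DEFAULT, Config


def describe(values):
    """(median, 25th centile, 75th centile) with linear interpolation (type 7)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot describe an empty sample")
    return (
        float(np.median(values)),
        float(np.percentile(values, 25)),
        float(np.percentile(values, 75)),
    )


def anderson_normal(values, alpha: float = DEFAULT.ad_alpha) -> bool:
    """True when the Anderson-Darling test does not reject normality at alpha."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("Anderson-Darling needs at least 4 observations")
    if np.ptp(values) == 0:
        return False  # degenerate sample; the AD statistic is undefined
    result = sps.anderson(values, dist="norm", method="interpolate")
    return bool(result.pvalue > alpha)


def ranksum_test(a, b):
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration for small samples (both n <= 8, no ties); normal
    approximation with continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    if max(a.size, b.size) <= 8 and not ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


@dataclass
class PopulationComparison:
    group_a: str
    group_b: str
    measure: str
    test: str | None
    statistic: float | None
    p: float | None
    median_a: float
    q25_a: float
    q75_a: float
    median_b: float
    q25_b: float
    q75_b: float
    normal_a: bool
    normal_b: bool
    degenerate: bool = False
    seed: int | None = None
    values_a: np.ndarray | None = field(default=None, repr=False)
    values_b: np.ndarray | None = field(default=None, repr=False)

    @property
    def tier(self) -> str:
        """Printed significance marker: '*' for p<0.01, '**' for p<0.001."""
        if self.p is None:
            return ""
        if self.p < 0.001:
            return "**"
        if self.p < 0.01:
            return "*"
        return ""


def compare_per_protein(
    values_a,
    values_b,
    *,
    names=("A", "B"),
    measure: str = "",
    config: Config = DEFAULT,
) -> PopulationComparison:
    """Compare two groups of per-protein values with the gated test.

    Both groups need at least 4 observations (the Anderson-Darling gate is
    unstable below that).  If every value in both groups is identical the
    comparison is degenerate: no test is run and the flag is set.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 4 or b.size < 4:
        raise ValueError("each group needs at least 4 values")
    med_a, q25_a, q75_a = describe(a)
    med_b, q25_b, q75_b = describe(b)
    degenerate = np.ptp(np.concatenate([a, b])) == 0
    if degenerate:
        test = statistic = p = None
        normal_a = normal_b = False
    else:
        normal_a = anderson_normal(a, config.ad_alpha)
        normal_b = anderson_normal(b, config.ad_alpha)
        if normal_a and normal_b:
            res = sps.ttest_ind(a, b)
            test, statistic, p = "t", float(res.statistic), float(res.pvalue)
        else:
            statistic, p = ranksum_test(a, b)
            test = "wilcoxon"
    return PopulationComparison(
        group_a=names[0],
        group_b=names[1],
        measure=measure,
        test=test,
        statistic=statistic,
        p=p,
        median_a=med_a,
        q25_a=q25_a,
        q75_a=q75_a,
        median_b=med_b,
        q25_b=q25_b,
        q75_b=q75_b,
        normal_a=normal_a if not degenerate else False,
        normal_b=normal_b if not degenerate else False,
        degenerate=bool(degenerate),
        values_a=a,
        values_b=b,
    )


def subset_measures(cohort, measure_fn, n_subsets, fraction, rng) -> np.ndarray:
    """Evaluate a population measure on independent random half-subsets.

    Subsets are drawn without replacement within each subset and
    independently across subsets, so a protein may appear in several of
    them.
    """
    cohort = list(cohort)
    k = int(round(len(cohort) * fraction))
    if k < 2:
        raise ValueError("cohort too small for half-subsets of size >= 2")
    values = np.empty(n_subsets)
    for i in range(n_subsets):
        idx = rng.choice(len(cohort), size=k, replace=False)
        values[i] = measure_fn([cohort[j] for j in idx])
    return values


def compare_population_measure(
    cohort_a,
    cohort_b,
    measure_fn,
    *,
    n_subsets: int = DEFAULT.n_subsets,
    fraction: float = DEFAULT.subset_fraction,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    names=("A", "B"),
    measure: str = "",
    config: Config = DEFAULT,
) -> PopulationComparison:
    """Resampling comparison of a population-level measure.

    ``measure_fn`` maps a list of proteins to one number (e.g. the fraction
    of fully disordered proteins).  It is evaluated on ``n_subsets`` random
    subsets containing ``fraction`` of each cohort, and the two value
    vectors are compared with the same normality-gated protocol as
    per-protein measurements.  Bit-reproducible given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    values_a = subset_measures(cohort_a, measure_fn, n_subsets, fraction, rng)
    values_b = subset_measures(cohort_b, measure_fn, n_subsets, fraction, rng)
    comparison = compare_per_protein(
        values_a, values_b, names=names, measure=measure, config=config
    )
    comparison.seed = seed
    return comparison
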