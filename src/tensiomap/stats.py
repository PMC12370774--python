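"""Two-group comparison pathway: normality battery, then t or Mann–Whitney.

Each sample first runs a four-test normality battery (D'Agostino–Pearson,
Anderson–Darling, Shapiro–Wilk, Lilliefors-corrected Kolmogorov–Smirnov).
A sample is called parametric when at least 3 of the 4 tests do not reject
at alpha (majority voting avoids the KS test's oversensitivity at large
n; an all-4 rule is available). Two parametric groups are compared with
the unpaired Student's t test (pooled variance; Welch by flag), anything
else with the two-sided Mann–Whitney test — exact when the pooled sample
is small and tie-free, normal approximation with tie correction
otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import kstest_normal, normal_ad

from ._errors import ConfigError

__all__ = [
    "NormalityReport",
    "ComparisonResult",
    "normality_battery",
    "compare_groups",
    "mann_whitney_exact_p",
    "significance_stars",
]

NORMALITY_TESTS = (
    "dagostino_pearson",
    "anderson_darling",
    "shapiro_wilk",
    "kolmogorov_smirnov",
)

MIN_N_FOR_BATTERY = 8
EXACT_MW_MAX_N = 20


@dataclass
class NormalityReport:
    tests: dict  # name -> (statistic, p_value)
    n: int
    alpha: float
    passes: int
    parametric: bool
    warnings: list = field(default_factory=list)


@dataclass
class ComparisonResult:
    test_name: str  # "unpaired_t" | "mann_whitney"
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    stars: str
    normality_a: NormalityReport | None = None
    normality_b: NormalityReport | None = None


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def normality_battery(sample, alpha: float = 0.05, rule: str = "majority") -> NormalityReport:
    """Run the four-test battery and produce a parametric/non-parametric verdict.

    ``rule="majority"``: parametric iff >= 3 of 4 tests fail to reject at
    ``alpha``; ``rule="all"``: all 4 must pass. Samples with n < 8 or zero
    variance get a non-parametric verdict with a warning (the tests are
    unstable or undefined there) rather than an error.
    """
    if rule not in {"majority", "all"}:
        raise ConfigError(f"unknown battery rule {rule!r}")
    x = np.asarray(sample, dtype=float).ravel()
    n = x.size
    warns: list = []
    if n < MIN_N_FOR_BATTERY:
        warns.append(f"n={n} < {MIN_N_FOR_BATTERY}: normality not assessable, verdict non-parametric")
        return NormalityReport({}, n, alpha, 0, False, warns)
    if np.ptp(x) == 0:
        warns.append("constant sample: verdict non-parametric")
        return NormalityReport({}, n, alpha, 0, False, warns)
    tests = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s, p = sps.normaltest(x)
        tests["dagostino_pearson"] = (float(s), float(p))
        s, p = normal_ad(x)
        tests["anderson_darling"] = (float(s), float(p))
        s, p = sps.shapiro(x)
        tests["shapiro_wilk"] = (float(s), float(p))
        s, p = kstest_normal(x, dist="norm")
        tests["kolmogorov_smirnov"] = (float(s), float(p))
    passes = sum(p > alpha for _, p in tests.values())
    parametric = passes >= (4 if rule == "all" else 3)
    return NormalityReport(tests, n, alpha, passes, parametric, warns)


def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank assignments giving each U value, tie-free case.

    counts[u] over u = 0..n1*n2, built by the classical recursion
    c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u).
    """
    # table[j] = counts array for (i, j) at current i
    prev = [np.ones(1, dtype=float) for _ in range(n2 + 1)]  # i = 0
    for i in range(1, n1 + 1):
        cur = [np.zeros(i * j + 1, dtype=float) for j in range(n2 + 1)]
        cur[0][0] = 1.0
        for j in range(1, n2 + 1):
            a = np.zeros(i * j + 1, dtype=float)
            a[j:][: (i - 1) * j + 1] += prev[j]  # first-group element ranked last: U += j
            a[: i * (j - 1) + 1] += cur[j - 1]
            cur[j] = a
        prev = cur
    return prev[n2]


def mann_whitney_exact_p(a, b) -> tuple:
    """Exact two-sided Mann–Whitney p via the U null distribution.

    Assumes no ties in the pooled sample. Returns ``(U1, p)`` with
    p = min(1, 2·min(P(U <= u), P(U >= u))).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size != pooled.size:
        raise ValueError("exact Mann-Whitney p requires a tie-free pooled sample")
    ranks = sps.rankdata(pooled)
    n1, n2 = a.size, b.size
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    counts = _u_null_counts(n1, n2)
    total = counts.sum()
    u = int(round(u1))
    cdf = counts[: u + 1].sum() / total
    sf = counts[u:].sum() / total
    return u1, float(min(1.0, 2.0 * min(cdf, sf)))


def compare_groups(
    a,
    b,
    alpha: float = 0.05,
    force: str | None = None,
    welch: bool = False,
    battery_rule: str = "majority",
) -> ComparisonResult:
    """Compare two independent groups the way the pipeline's figures do.

    Test selection follows the normality battery of both groups unless
    ``force`` is ``"t"`` or ``"mann_whitney"``. Significance stars:
    * < 0.05, ** < 0.01, *** < 0.001.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size < 2 or b.size < 2:
        raise ConfigError("each group needs at least 2 observations")
    rep_a = rep_b = None
    if force is None:
        rep_a = normality_battery(a, alpha, battery_rule)
        rep_b = normality_battery(b, alpha, battery_rule)
        use_t = rep_a.parametric and rep_b.parametric
    elif force == "t":
        use_t = True
    elif force == "mann_whitney":
        use_t = False
    else:
        raise ConfigError(f"unknown force value {force!r}")

    if use_t:
        name = "unpaired_t"
        if np.ptp(np.concatenate([a, b])) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_ind(a, b, equal_var=not welch)
    else:
        name = "mann_whitney"
        pooled = np.concatenate([a, b])
        tie_free = np.unique(pooled).size == pooled.size
        if tie_free and pooled.size <= EXACT_MW_MAX_N:
            stat, p = mann_whitney_exact_p(a, b)
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        n_a=a.size,
        n_b=b.size,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        stars=significance_stars(float(p)),
        normality_a=rep_a,
        normality_b=rep_b,
    )
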