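"""Statistical layer: normality-routed paired comparisons, ICC(A,1)
reliability, and paired-t sample-size calculation.

Distribution functions (Shapiro-Wilk, t, Wilcoxon null, F, noncentral t)
are delegated to scipy.stats; the routing logic, the two-way ANOVA
mean-square decomposition behind the ICC, and the power search are
implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError

__all__ = [
    "PairedComparison",
    "ICCResult",
    "paired_compare",
    "icc_a1",
    "sample_size_paired_t",
]


@dataclass(frozen=True)
class PairedComparison:
    """Two-sided paired comparison routed by a Shapiro-Wilk normality test.

    ``test_used`` is ``"paired_t"`` when the Shapiro-Wilk p-value on the
    paired differences exceeds the routing alpha, ``"wilcoxon"`` otherwise,
    and ``"degenerate"`` for identical vectors (p = 1 by convention).
    """

    n: int
    mean_sd_a: tuple
    mean_sd_b: tuple
    test_used: str
    statistic: float
    p_value: float
    normality_p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def _mean_sd(x: np.ndarray) -> tuple:
    return float(np.mean(x)), float(np.std(x, ddof=1))


def paired_compare(a, b, alpha: float = 0.05, test: str = "auto",
                   ) -> PairedComparison:
    """Compare paired samples ``a`` (baseline) and ``b`` two-sidedly.

    With ``test="auto"`` the differences ``b - a`` are routed by a
    Shapiro-Wilk test at the routing ``alpha``: normal-looking differences
    go to the paired t test, otherwise to the Wilcoxon signed-rank test
    (zeros dropped; exact null for n <= 25 without ties, normal
    approximation with continuity correction above).  ``test`` may force
    ``"paired_t"`` or ``"wilcoxon"``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D vectors of equal length")
    if a.size < 3:
        raise ValueError("at least 3 pairs required")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("inputs must be finite")
    d = b - a

    if np.all(d == d[0]):
        if d[0] == 0.0:
            return PairedComparison(a.size, _mean_sd(a), _mean_sd(b),
                                    "degenerate", 0.0, 1.0, float("nan"))
        raise DegenerateDataError(
            "paired differences are constant and non-zero: no valid test")

    normality_p = float(stats.shapiro(d).pvalue)
    if test == "auto":
        test = "paired_t" if normality_p > alpha else "wilcoxon"
    if test == "paired_t":
        res = stats.ttest_1samp(d, 0.0, alternative="two-sided")
        statistic, p = float(res.statistic), float(res.pvalue)
    elif test == "wilcoxon":
        d_nz = d[d != 0]
        unique, counts = np.unique(np.abs(d_nz), return_counts=True)
        has_ties = np.any(counts > 1)
        method = "exact" if (d_nz.size <= 25 and not has_ties) else "approx"
        res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                             alternative="two-sided", method=method)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return PairedComparison(a.size, _mean_sd(a), _mean_sd(b), test,
                            statistic, min(p, 1.0), normality_p)


@dataclass(frozen=True)
class ICCResult:
    """ICC(A,1): two-way model, single rater, absolute agreement."""

    icc: float
    ci95: tuple
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int


def icc_a1(ratings, confidence: float = 0.95) -> ICCResult:
    """Intraclass correlation ICC(A,1) with an F-based confidence interval.

    ``ratings`` is an n-subjects x k-raters matrix with no missing cells.
    Mean squares come from the two-way ANOVA decomposition
    (rows = subjects, columns = raters) and

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).

    The confidence interval uses the standard F approximation with
    Satterthwaite degrees of freedom for the denominator.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an (n >= 2) x (k >= 2) matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings must be finite (no missing cells)")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise DegenerateDataError("constant ratings matrix: ICC undefined")
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if icc >= 1.0 or (mse == 0 and msc == 0):
        ci = (1.0, 1.0) if icc >= 1.0 else (icc, icc)
        return ICCResult(float(icc), ci, float(msr), float(msc), float(mse), n, k)

    a = k * icc / (n * (1.0 - icc))
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc))
    num_v = (a * msc + b * mse) ** 2
    den_v = ((a * msc) ** 2 / (k - 1)
             + (b * mse) ** 2 / ((n - 1) * (k - 1)))
    v = num_v / den_v if den_v > 0 else (n - 1) * (k - 1)
    f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (n * (msr - f_low * mse)
             / (f_low * (k * msc + (k * n - k - n) * mse) + n * msr))
    upper = (n * (f_up * msr - mse)
             / (k * msc + (k * n - k - n) * mse + n * f_up * msr))
    return ICCResult(float(icc), (float(lower), float(upper)),
                     float(msr), float(msc), float(mse), n, k)


def _paired_t_power(n: int, d: float, alpha: float) -> float:
    df = n - 1
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    nc = d * math.sqrt(n)
    return float(1.0 - stats.nct.cdf(tcrit, df, nc)
                 + stats.nct.cdf(-tcrit, df, nc))


def sample_size_paired_t(effect_size: float, alpha: float = 0.05,
                         power: float = 0.95, n_max: int = 100000) -> int:
    """Smallest n with noncentral-t power >= ``power`` for a paired t test.

    ``effect_size`` is Cohen's d_z, the mean paired difference divided by
    the SD of the differences; the noncentrality parameter is d_z*sqrt(n).
    """
    if effect_size <= 0:
        raise ValueError("effect_size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        if _paired_t_power(n, effect_size, alpha) >= power:
            return n
    raise ValueError(f"required n exceeds {n_max} for d = {effect_size}")
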