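"""Intra- and interpatient heterogeneity of fitted Gompertz parameters.

Fitted cohorts are summarized by: lognormality of the initial growth rate
a (one-sample KS test of log10(a) against a fitted normal), the fraction
of "exponential organoids" (b at its 1e-4 floor), the a-b correlation
among nonexponential fits, carrying-capacity category proportions, the
dormancy-time histogram, and Day-0/Day-5 growth-rate summaries.  Group
comparisons use pairwise two-sample KS tests with an optional Bonferroni
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitResult
from .models import K_CAP

__all__ = [
    "K_CATEGORIES",
    "HeterogeneityReport",
    "test_lognormality",
    "compare_groups_ks",
    "carrying_capacity_summary",
    "correlation_ab",
    "rate_at_day",
    "smoothed_cdf",
    "position_effect",
    "tau_histogram",
    "summarize_cohort",
]

#: Carrying-capacity category edges (cells): <10, 10-1e2, 1e2-1e3, 1e3-1e4, >=1e4.
K_CATEGORIES = (
    ("K<10", 0.0, 10.0),
    ("10<=K<1e2", 10.0, 1e2),
    ("1e2<=K<1e3", 1e2, 1e3),
    ("1e3<=K<1e4", 1e3, 1e4),
    ("K>=1e4", 1e4, math.inf),
)


def _gompertz_fits(fits: Sequence[FitResult]) -> list[FitResult]:
    out = [f for f in fits if f.spec.family == "gompertz"]
    if not out:
        raise ValueError("no Gompertz fits supplied")
    return out


def test_lognormality(
    values: Sequence[float],
    alpha: float = 0.05,
    mu: float | None = None,
    sigma: float | None = None,
    lilliefors: bool = False,
) -> tuple[float, float, bool]:
    """One-sample KS test of log10(values) against a normal distribution.

    By default the normal's mean and s.d. are estimated from the sample
    itself, mirroring the usual practice; note that reusing the data to
    estimate the parameters makes the plain KS p-value conservative.  Pass
    ``mu``/``sigma`` to test against a fixed normal (nominal behavior), or
    ``lilliefors=True`` for the estimated-parameter correction.

    Returns (statistic, p_value, reject at level alpha).
    """
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ValueError("values must be positive to take logarithms")
    if x.size < 8:
        import warnings

        warnings.warn("fewer than 8 values; the KS test has little power",
                      stacklevel=2)
    logx = np.log10(x)
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(logx, dist="norm")
        return float(stat), float(p), bool(p < alpha)
    m = logx.mean() if mu is None else mu
    s = logx.std(ddof=1) if sigma is None else sigma
    if s <= 0:
        raise ValueError("degenerate sample: zero standard deviation")
    stat, p = stats.kstest(logx, "norm", args=(m, s))
    return float(stat), float(p), bool(p < alpha)


def compare_groups_ks(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> pd.DataFrame:
    """Pairwise two-sample KS tests between named samples.

    With ``bonferroni`` the significance threshold is alpha divided by the
    number of pairs.  Returns a tidy frame with columns group1, group2,
    statistic, p_value, significant.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups to compare")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    threshold = alpha / len(pairs) if bonferroni else alpha
    rows = []
    for g1, g2 in pairs:
        x, y = np.asarray(groups[g1], float), np.asarray(groups[g2], float)
        if x.size == 0 or y.size == 0:
            raise ValueError("groups must be nonempty")
        stat, p = stats.ks_2samp(x, y)
        rows.append({"group1": g1, "group2": g2, "statistic": float(stat),
                     "p_value": float(p), "significant": bool(p < threshold)})
    return pd.DataFrame(rows)


def carrying_capacity_summary(fits: Sequence[FitResult]) -> dict[str, float]:
    """Proportion of nonexponential Gompertz fits in each carrying-capacity
    category (K capped at 1e10); empty dict when every fit is exponential."""
    gf = _gompertz_fits(fits)
    ks = np.array([min(f.K_hat, K_CAP) for f in gf if not f.is_exponential])
    if ks.size == 0:
        return {}
    return {
        label: float(np.mean((ks >= lo) & (ks < hi)))
        for label, lo, hi in K_CATEGORIES
    }


def correlation_ab(fits: Sequence[FitResult], scale: str = "raw") -> float:
    """Pearson correlation of (a, b) over nonexponential Gompertz fits,
    on the raw or log10 scale."""
    gf = [f for f in _gompertz_fits(fits) if not f.is_exponential]
    if len(gf) < 3:
        raise ValueError("need at least 3 nonexponential fits")
    a = np.array([f.params["a"] for f in gf])
    b = np.array([f.params["b"] for f in gf])
    if scale == "log10":
        a, b = np.log10(a), np.log10(b)
    elif scale != "raw":
        raise ValueError("scale must be 'raw' or 'log10'")
    return float(stats.pearsonr(a, b)[0])


def rate_at_day(fit: FitResult, day: float) -> float:
    """Gompertz growth rate a*exp(-b*(tau + day)) on experiment Day
    ``day`` (model time of Day d is tau + d)."""
    if fit.spec.family != "gompertz":
        raise ValueError("day rates are defined for Gompertz fits")
    p = fit.params
    return p["a"] * math.exp(-p["b"] * (fit.tau_hat + day))


def smoothed_cdf(
    values: Sequence[float], grid: Sequence[float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel-smoothed empirical CDF.

    Bandwidth follows Silverman's rule; the default grid is 512 equally
    spaced points spanning the data +- 3 bandwidths.  Returns (grid, cdf)
    with cdf nondecreasing in [0, 1].
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    s = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    sigma = min(s, iqr / 1.349) if iqr > 0 else s
    if sigma == 0:
        sigma = max(abs(x[0]), 1.0) * 1e-3  # degenerate sample: narrow kernel
    h = 0.9 * sigma * x.size ** (-0.2)
    if grid is None:
        grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, 512)
    else:
        grid = np.asarray(grid, dtype=float)
    cdf = stats.norm.cdf((grid[:, None] - x[None, :]) / h).mean(axis=1)
    return grid, cdf


def position_effect(
    fits: Sequence[FitResult],
    positions: Sequence[float],
    response: str = "a",
) -> tuple[float, tuple[float, float], bool]:
    """OLS regression of a fitted quantity on the distance r from the well
    center; tests whether organoid position drives the heterogeneity.

    ``response`` is "a" (initial growth rate) or "K" (carrying capacity,
    capped at 1e10).  Returns (slope, 95% CI, significant), where
    significant means the CI excludes zero.
    """
    import statsmodels.api as sm

    gf = _gompertz_fits(fits)
    r = np.asarray(positions, dtype=float)
    if r.size != len(gf):
        raise ValueError("positions must align with fits")
    if r.size < 3:
        raise ValueError("need at least 3 points")
    if response == "a":
        y = np.array([f.params["a"] for f in gf])
    elif response == "K":
        y = np.array([min(f.K_hat, K_CAP) for f in gf])
    else:
        raise ValueError("response must be 'a' or 'K'")
    model = sm.OLS(y, sm.add_constant(r)).fit()
    slope = float(model.params[1])
    lo, hi = map(float, model.conf_int(alpha=0.05)[1])
    return slope, (lo, hi), not (lo <= 0.0 <= hi)


def tau_histogram(
    fits: Sequence[FitResult], tau_max: float = 4.0, bins: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of fitted dormancy times on [0, tau_max]."""
    taus = [f.tau_hat for f in _gompertz_fits(fits)]
    return np.histogram(taus, bins=bins, range=(0.0, tau_max))


@dataclass(frozen=True)
class HeterogeneityReport:
    """Cohort-level heterogeneity summary of Gompertz fits."""

    n_organoids: int
    log10_a_mean: float
    log10_a_sd: float
    ks_statistic: float
    ks_p_value: float
    lognormal_rejected: bool
    proportion_exponential: float
    correlation_ab_raw: float | None
    correlation_ab_log10: float | None
    k_category_proportions: dict[str, float]
    tau_hist_counts: tuple[int, ...]
    tau_hist_edges: tuple[float, ...]
    day0_rate_median: float
    day5_rate_median: float

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["tau_hist_counts"] = list(self.tau_hist_counts)
        d["tau_hist_edges"] = list(self.tau_hist_edges)
        return d


def summarize_cohort(
    fits: Sequence[FitResult], tau_max: float = 4.0, alpha: float = 0.05
) -> HeterogeneityReport:
    """Full per-cohort heterogeneity report from Gompertz fits."""
    gf = _gompertz_fits(fits)
    a = np.array([f.params["a"] for f in gf])
    log_a = np.log10(a)
    stat, p, reject = test_lognormality(a, alpha=alpha)
    n_nonexp = sum(not f.is_exponential for f in gf)
    corr_raw = corr_log = None
    if n_nonexp >= 3:
        corr_raw = correlation_ab(gf, "raw")
        corr_log = correlation_ab(gf, "log10")
    counts, edges = tau_histogram(gf, tau_max=tau_max)
    return HeterogeneityReport(
        n_organoids=len(gf),
        log10_a_mean=float(log_a.mean()),
        log10_a_sd=float(log_a.std(ddof=1)),
        ks_statistic=stat,
        ks_p_value=p,
        lognormal_rejected=reject,
        proportion_exponential=float(np.mean([f.is_exponential for f in gf])),
        correlation_ab_raw=corr_raw,
        correlation_ab_log10=corr_log,
        k_category_proportions=carrying_capacity_summary(gf),
        tau_hist_counts=tuple(int(c) for c in counts),
        tau_hist_edges=tuple(float(e) for e in edges),
        day0_rate_median=float(np.median([rate_at_day(f, 0.0) for f in gf])),
        day5_rate_median=float(np.median([rate_at_day(f, 5.0) for f in gf])),
    )
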