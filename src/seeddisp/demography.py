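"""Size-class demography and exact/contingency statistics.

Census cohorts follow fixed dbh thresholds (small sapling < 5 cm, large
sapling 5-10 cm, adult >= 10 cm).  Regeneration comparisons use the
two-sample Kolmogorov-Smirnov test on dbh distributions, Greenwood pointwise
bands around empirical CDFs, Fisher's exact test with the conditional-ML
odds ratio (the convention under which a zero cell yields OR = 0), and a
relative prevalence-reduction contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .population import ADULT_MIN_DBH, SMALL_SAPLING_MAX_DBH, cohort_from_dbh


@dataclass
class SizeClassTable:
    """Standardized dbh histogram (2-cm bins) with cohort totals per site."""

    bin_edges: np.ndarray
    counts: pd.DataFrame          # rows = bins, columns = sites
    frequencies: pd.DataFrame     # counts standardized per site (sum to 1)
    cohort_totals: pd.DataFrame   # rows = cohorts, columns = sites

    def pooled(self, sites: list[str]) -> pd.Series:
        """Pooled regime frequencies = average of site frequencies weighted by
        site census size."""
        w = self.counts[sites].sum(axis=0)
        return (self.frequencies[sites] * w).sum(axis=1) / w.sum()


def size_class_histogram(dbh: np.ndarray, site: np.ndarray,
                         bin_width: float = 2.0,
                         max_dbh: float | None = None) -> SizeClassTable:
    """Per-site standardized dbh histogram and cohort totals."""
    dbh = np.asarray(dbh, float)
    site = np.asarray(site, object)
    if np.any(dbh < 0) or np.any(~np.isfinite(dbh)):
        raise ValueError("dbh values must be finite and >= 0")
    top = max_dbh if max_dbh is not None else (np.ceil(dbh.max() / bin_width)
                                               * bin_width + bin_width)
    edges = np.arange(0, top + bin_width / 2, bin_width)
    sites = list(pd.unique(site))
    counts = pd.DataFrame(
        {s: np.histogram(dbh[site == s], bins=edges)[0] for s in sites})
    freqs = counts / counts.sum(axis=0)
    cohorts = pd.DataFrame(
        {s: pd.Series([cohort_from_dbh(d) for d in dbh[site == s]])
            .value_counts().reindex(["small_sapling", "large_sapling", "adult"],
                                    fill_value=0)
         for s in sites})
    return SizeClassTable(edges, counts, freqs, cohorts)


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-tailed two-sample Kolmogorov-Smirnov test.

    D = sup |ECDF_a - ECDF_b|; the p-value is exact (enumeration) when the
    smaller sample has <= 10 observations, asymptotic otherwise.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if min(len(a), len(b)) <= 10 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def ecdf_greenwood_band(sample: np.ndarray, alpha: float = 0.05
                        ) -> pd.DataFrame:
    """ECDF with pointwise Greenwood CIs, variance F(1-F)/n, clipped to [0,1]."""
    x = np.sort(np.asarray(sample, float))
    n = len(x)
    if n < 1:
        raise ValueError("empty sample")
    f = np.arange(1, n + 1) / n
    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(f * (1 - f) / n)
    lo = np.maximum.accumulate(np.clip(f - z * se, 0.0, 1.0))
    hi = np.maximum.accumulate(np.clip(f + z * se, 0.0, 1.0))
    return pd.DataFrame({"x": x, "ecdf": f, "ci_low": lo, "ci_high": hi})


# ---------------------------------------------------------------------------
# Fisher's exact test with conditional-MLE odds ratio


def _nchg_probs(N: int, n1: int, m: int, log_psi: float
                ) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of Fisher's noncentral hypergeometric
    distribution with odds exp(log_psi), computed from log-binomial weights."""
    lo, hi = max(0, m - (N - n1)), min(m, n1)
    xs = np.arange(lo, hi + 1)
    logw = (gammaln(n1 + 1) - gammaln(xs + 1) - gammaln(n1 - xs + 1)
            + gammaln(N - n1 + 1) - gammaln(m - xs + 1)
            - gammaln(N - n1 - m + xs + 1) + xs * log_psi)
    w = np.exp(logw - logw.max())
    return xs, w / w.sum()


def _cmle_or(table: np.ndarray) -> float:
    """Conditional MLE of the odds ratio under the noncentral hypergeometric
    likelihood (the R fisher.test convention)."""
    a = int(table[0, 0])
    m = int(table[0].sum())        # first-row margin (draws)
    n1 = int(table[:, 0].sum())    # first-column margin (success states)
    N = int(table.sum())
    lo, hi = max(0, m - (N - n1)), min(m, n1)
    if a == lo:
        return 0.0
    if a == hi:
        return np.inf

    def mean_minus_a(log_psi):
        xs, p = _nchg_probs(N, n1, m, log_psi)
        return float(np.sum(xs * p)) - a

    return float(np.exp(optimize.brentq(mean_minus_a, -50, 50, xtol=1e-12)))


def fisher_exact(table, ci: bool = True
                 ) -> tuple[float, tuple[float, float], float]:
    """Fisher's exact test: (conditional-MLE OR, exact 95% CI, two-tailed p).

    The CI inverts the exact one-sided tail tests of the noncentral
    hypergeometric distribution (skipped, returned as (nan, nan), when
    ``ci=False``); p sums the probabilities of all tables as or less probable
    than the observed one.
    """
    t = np.asarray(table, int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate margin; odds ratio undefined")
    a = int(t[0, 0])
    m, n1, N = int(t[0].sum()), int(t[:, 0].sum()), int(t.sum())
    lo_sup, hi_sup = max(0, m - (N - n1)), min(m, n1)

    orr = _cmle_or(t)
    p = float(stats.fisher_exact(t)[1])
    if not ci:
        return orr, (np.nan, np.nan), p

    def sf_at(log_psi):   # P(X >= a | psi)
        xs, p = _nchg_probs(N, n1, m, log_psi)
        return float(p[xs >= a].sum())

    def cdf_at(log_psi):  # P(X <= a | psi)
        xs, p = _nchg_probs(N, n1, m, log_psi)
        return float(p[xs <= a].sum())

    alpha = 0.05
    if a == lo_sup:
        ci_low = 0.0
    else:
        ci_low = float(np.exp(optimize.brentq(
            lambda lp: sf_at(lp) - alpha / 2, -50, 50)))
    if a == hi_sup:
        ci_high = np.inf
    else:
        ci_high = float(np.exp(optimize.brentq(
            lambda lp: cdf_at(lp) - alpha / 2, -50, 50)))
    return orr, (ci_low, ci_high), p


def prevalence_contrast(successes1: int, trials1: int,
                        successes2: int, trials2: int,
                        alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Relative prevalence reduction 1 - p2/p1 with a log-ratio normal CI.

    Group 1 is the reference (e.g. elephant-present forests); the statistic is
    the proportional drop in prevalence in group 2.
    """
    if trials1 <= 0 or trials2 <= 0:
        raise ValueError("trials must be positive")
    p1, p2 = successes1 / trials1, successes2 / trials2
    if p1 == 0:
        raise ZeroDivisionError("reference prevalence is zero; ratio undefined")
    if p2 == 0:
        return 1.0, (np.nan, 1.0)
    log_ratio = np.log(p2 / p1)
    se = np.sqrt((1 - p1) / (trials1 * p1) + (1 - p2) / (trials2 * p2))
    z = stats.norm.ppf(1 - alpha / 2)
    lo_ratio, hi_ratio = np.exp(log_ratio - z * se), np.exp(log_ratio + z * se)
    return 1 - p2 / p1, (1 - hi_ratio, 1 - lo_ratio)
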