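"""Fine-scale spatial genetic structure from pairwise kinship.

Pairwise kinship uses the Loiselle/Nason product-moment estimator referenced
to a supplied allele-frequency table; the strength of structure is summarised
by the Sp statistic, Sp = -b_Ld / (1 - F1), where b_Ld is the regression
slope of pairwise kinship on ln(distance) and F1 the mean kinship in the
first distance class.  Uncertainty comes from jackknifing loci; significance
from permuting spatial positions against genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .population import MISSING, AlleleFrequencyTable, Population, as_population

DEFAULT_BIN_EDGES = (0.0, 30.0, 100.0, 200.0, 400.0, 800.0, 1600.0, 3200.0)


class UndefinedKinshipError(ValueError):
    pass


# ---------------------------------------------------------------------------
# kinship internals


class _KinshipTables:
    """Per-locus kinship numerators/denominators for all pairs of a population.

    For locus l with reference frequencies p_a and dosage x_ia (half the count
    of allele a in individual i):

        num_l(i,j) = sum_a (x_ia - p_a)(x_ja - p_a) + sum_a p_a(1-p_a)/(n_l-1)
        den_l      = sum_a p_a(1-p_a)

    The multilocus kinship is the ratio of summed numerators to summed
    denominators over loci non-missing in both individuals.
    """

    def __init__(self, pop: Population, afreq: AlleleFrequencyTable):
        loci = [l for l in pop.loci if l in afreq.freqs]
        if not loci:
            raise UndefinedKinshipError("no loci shared with the frequency table")
        n = len(pop)
        self.loci = loci
        self.num = np.empty((len(loci), n, n))
        self.den = np.empty(len(loci))
        self.valid = np.empty((len(loci), n), bool)
        for k, locus in enumerate(loci):
            l = pop.loci.index(locus)
            alleles = afreq.alleles(locus)
            p = afreq.freq_array(locus)
            g = pop.genotypes[:, l, :]
            ok = (g != MISSING).all(axis=1)
            x = 0.5 * ((g[:, 0, None] == alleles[None, :]).astype(float)
                       + (g[:, 1, None] == alleles[None, :]))
            c = np.where(ok[:, None], x - p[None, :], 0.0)
            n_l = afreq.n_genes.get(locus, 0)
            corr = float(np.sum(p * (1 - p)) / (n_l - 1)) if n_l > 1 else 0.0
            self.num[k] = c @ c.T + corr
            self.den[k] = float(np.sum(p * (1 - p)))
            self.valid[k] = ok

    def pair_valid(self) -> np.ndarray:
        """(L, n, n) loci usable for each pair."""
        return self.valid[:, :, None] & self.valid[:, None, :]

    def multilocus(self, drop_locus: int | None = None) -> np.ndarray:
        """(n, n) multilocus kinship; optionally with one locus deleted."""
        keep = np.ones(len(self.loci), bool)
        if drop_locus is not None:
            keep[drop_locus] = False
        pv = self.pair_valid()[keep]
        num = np.where(pv, self.num[keep], 0.0).sum(axis=0)
        den = (pv * self.den[keep, None, None]).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(den > 0, num / den, np.nan)

    def per_locus(self, k: int) -> np.ndarray:
        pv = self.pair_valid()[k]
        with np.errstate(invalid="ignore"):
            return np.where(pv, self.num[k] / self.den[k], np.nan)


def pairwise_kinship(ind_i, ind_j, afreq: AlleleFrequencyTable
                     ) -> tuple[float, dict[str, float]]:
    """Multilocus Loiselle/Nason kinship between two individuals.

    Returns ``(F_ij, per_locus)``; raises if the pair shares no genotyped
    locus present in the frequency table.
    """
    pop = Population.from_individuals([ind_i, ind_j], loci=list(afreq.loci))
    tab = _KinshipTables(pop, afreq)
    shared = tab.pair_valid()[:, 0, 1]
    if not shared.any():
        raise UndefinedKinshipError("individuals share no genotyped locus")
    per_locus = {tab.loci[k]: float(tab.per_locus(k)[0, 1])
                 for k in range(len(tab.loci)) if shared[k]}
    return float(tab.multilocus()[0, 1]), per_locus


# ---------------------------------------------------------------------------
# curves and Sp


@dataclass
class KinshipCurve:
    """Distance-binned kinship with jackknife errors and Sp inference fields."""

    bin_edges: np.ndarray
    f_mean: np.ndarray              # per-bin mean multilocus kinship (nan = empty)
    f_se: np.ndarray                # jackknife-over-loci SE per bin
    n_pairs: np.ndarray
    b_ld: float = np.nan            # slope of F_ij on ln(r_ij), all pairs r > 0
    b_ld_se: float = np.nan
    f1: float = np.nan              # mean kinship in the first distance class
    sp: float = np.nan
    sp_se: float = np.nan
    per_locus_slopes: np.ndarray = field(default_factory=lambda: np.array([]))
    loci: list = field(default_factory=list)
    envelope_low: np.ndarray | None = None     # per-bin permutation envelope
    envelope_high: np.ndarray | None = None
    sp_envelope: tuple[float, float] | None = None
    p_sp: float = np.nan
    p_bins: np.ndarray | None = None


def _pair_arrays(pop: Population):
    iu = np.triu_indices(len(pop), k=1)
    d = np.linalg.norm(pop.xy[iu[0]] - pop.xy[iu[1]], axis=1)
    return iu, d


def _bin_means(values: np.ndarray, bin_idx: np.ndarray, n_bins: int
               ) -> tuple[np.ndarray, np.ndarray]:
    ok = (bin_idx >= 0) & ~np.isnan(values)
    sums = np.bincount(bin_idx[ok], weights=values[ok], minlength=n_bins)
    counts = np.bincount(bin_idx[ok], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def _jackknife_se(estimates: np.ndarray) -> np.ndarray | float:
    """Delete-one jackknife SE from the L leave-one-out estimates."""
    L = len(estimates)
    if L < 2:
        return np.nan
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(estimates, axis=0)
    return np.sqrt((L - 1) / L * np.nansum((estimates - mean) ** 2, axis=0))


def _slope(f: np.ndarray, logd: np.ndarray) -> float:
    ok = ~np.isnan(f) & ~np.isnan(logd)
    if ok.sum() < 2:
        return np.nan
    x, y = logd[ok], f[ok]
    vx = x.var()
    if vx == 0:
        return np.nan
    return float(((x - x.mean()) * (y - y.mean())).mean() / vx)


def kinship_distance_curve(individuals, afreq: AlleleFrequencyTable,
                           bin_edges=DEFAULT_BIN_EDGES) -> KinshipCurve:
    """Mean pairwise kinship per distance class with jackknife-over-loci SEs."""
    pop = as_population(individuals)
    if len(pop) < 2:
        raise ValueError("need at least two individuals")
    edges = np.asarray(bin_edges, float)
    tab = _KinshipTables(pop, afreq)
    iu, d = _pair_arrays(pop)
    bin_idx = np.digitize(d, edges[1:], right=False)
    bin_idx[d >= edges[-1]] = -1
    n_bins = len(edges) - 1
    bin_idx[bin_idx >= n_bins] = -1

    f = tab.multilocus()[iu]
    means, counts = _bin_means(f, bin_idx, n_bins)
    loo = np.array([_bin_means(tab.multilocus(drop_locus=k)[iu], bin_idx, n_bins)[0]
                    for k in range(len(tab.loci))])
    se = _jackknife_se(loo) if len(tab.loci) >= 2 else np.full(n_bins, np.nan)
    return KinshipCurve(edges, means, np.asarray(se), counts, loci=tab.loci)


def sp_statistic(individuals, afreq: AlleleFrequencyTable,
                 first_bin_upper: float = 30.0,
                 bin_edges=DEFAULT_BIN_EDGES) -> KinshipCurve:
    """Kinship-distance curve plus b_Ld, F1, Sp and per-locus slopes.

    b_Ld regresses all pairwise kinship values (not bin means) on ln distance,
    excluding zero-distance pairs; Sp = -b_Ld / (1 - F1).
    """
    pop = as_population(individuals)
    curve = kinship_distance_curve(pop, afreq, bin_edges)
    tab = _KinshipTables(pop, afreq)
    iu, d = _pair_arrays(pop)
    with np.errstate(divide="ignore"):
        logd = np.where(d > 0, np.log(d), np.nan)
    f = tab.multilocus()[iu]

    first = d <= first_bin_upper
    if not (first & ~np.isnan(f)).any():
        raise ValueError(f"no pairs within {first_bin_upper} m; widen the first "
                         "distance class")
    f1 = float(np.nanmean(f[first]))
    if f1 >= 1:
        raise UndefinedKinshipError("mean first-class kinship >= 1; Sp undefined")
    b = _slope(f, logd)
    curve.b_ld, curve.f1 = b, f1
    curve.sp = -b / (1 - f1)

    curve.per_locus_slopes = np.array([_slope(tab.per_locus(k)[iu], logd)
                                       for k in range(len(tab.loci))])
    if len(tab.loci) >= 2:
        loo_b = np.empty(len(tab.loci))
        loo_sp = np.empty(len(tab.loci))
        for k in range(len(tab.loci)):
            fk = tab.multilocus(drop_locus=k)[iu]
            loo_b[k] = _slope(fk, logd)
            f1k = float(np.nanmean(fk[first]))
            loo_sp[k] = -loo_b[k] / (1 - f1k)
        curve.b_ld_se = float(_jackknife_se(loo_b))
        curve.sp_se = float(_jackknife_se(loo_sp))
    return curve


# ---------------------------------------------------------------------------
# permutation inference


def permutation_test_fsgs(individuals, afreq: AlleleFrequencyTable,
                          n_perm: int = 4999, alpha: float = 0.05,
                          seed: int | np.random.Generator = 0,
                          first_bin_upper: float = 30.0,
                          bin_edges=DEFAULT_BIN_EDGES) -> KinshipCurve:
    """Permutation envelopes and p-values for F(r) and Sp.

    Spatial positions are permuted against genotypes (null: no spatial genetic
    structure); envelopes are the alpha/2 and 1-alpha/2 empirical quantiles of
    the permuted statistics, and two-tailed p-values use the add-one rank rule.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pop = as_population(individuals)
    rng = np.random.default_rng(seed)
    curve = sp_statistic(pop, afreq, first_bin_upper, bin_edges)

    tab = _KinshipTables(pop, afreq)
    iu, _ = _pair_arrays(pop)
    f = tab.multilocus()[iu]
    n = len(pop)
    dmat = np.linalg.norm(pop.xy[:, None, :] - pop.xy[None, :, :], axis=2)
    edges = np.asarray(bin_edges, float)
    n_bins = len(edges) - 1

    perm_bins = np.empty((n_perm, n_bins))
    perm_sp = np.empty(n_perm)
    for t in range(n_perm):
        p = rng.permutation(n)
        d = dmat[p[iu[0]], p[iu[1]]]
        bi = np.digitize(d, edges[1:], right=False)
        bi[(d >= edges[-1]) | (bi >= n_bins)] = -1
        perm_bins[t], _ = _bin_means(f, bi, n_bins)
        with np.errstate(divide="ignore"):
            logd = np.where(d > 0, np.log(d), np.nan)
        b = _slope(f, logd)
        first = d <= first_bin_upper
        f1 = np.nanmean(f[first]) if (first & ~np.isnan(f)).any() else np.nan
        perm_sp[t] = -b / (1 - f1)

    lo, hi = alpha / 2, 1 - alpha / 2
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)   # bins empty in every permutation
        curve.envelope_low = np.nanquantile(perm_bins, lo, axis=0)
        curve.envelope_high = np.nanquantile(perm_bins, hi, axis=0)
    curve.sp_envelope = (float(np.nanquantile(perm_sp, lo)),
                         float(np.nanquantile(perm_sp, hi)))
    curve.p_sp = _two_tailed_p(curve.sp, perm_sp)
    curve.p_bins = np.array([_two_tailed_p(curve.f_mean[b], perm_bins[:, b])
                             for b in range(n_bins)])
    return curve


def _two_tailed_p(observed: float, permuted: np.ndarray) -> float:
    """Two-tailed permutation p with the add-one rule; >= 1/(n_perm+1)."""
    perm = permuted[~np.isnan(permuted)]
    if np.isnan(observed) or len(perm) == 0:
        return np.nan
    n = len(perm)
    ge = int(np.sum(perm >= observed))
    le = int(np.sum(perm <= observed))
    return min(1.0, 2.0 * (1 + min(ge, le)) / (n + 1))


# ---------------------------------------------------------------------------
# cross-cohort comparison


def compare_sp_paired_t(per_locus_slopes_a: np.ndarray,
                        per_locus_slopes_b: np.ndarray
                        ) -> tuple[float, int, float]:
    """Two-sided paired-sample t test on per-locus b_Ld slopes.

    A proxy for comparing Sp between two groups typed at the same loci:
    returns (t, df, p) with df = n_loci - 1.  A zero-variance difference
    vector yields the degenerate boundary p (0 if means differ, 1 otherwise).
    """
    a = np.asarray(per_locus_slopes_a, float)
    b = np.asarray(per_locus_slopes_b, float)
    if a.shape != b.shape:
        raise ValueError("slope vectors must match locus for locus")
    if len(a) < 2:
        raise ValueError("need at least two loci")
    diff = a - b
    df = len(diff) - 1
    if np.allclose(diff.std(ddof=1), 0.0):
        import warnings
        warnings.warn("zero variance of slope differences; p is degenerate",
                      stacklevel=2)
        return (0.0, df, 1.0) if np.allclose(diff.mean(), 0) else (np.inf, df, 0.0)
    t, p = stats.ttest_rel(a, b)
    return float(t), df, float(p)


def holm_adjust(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment for a family of comparisons."""
    p = np.asarray(p_values, float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
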