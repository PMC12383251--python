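"""Self-contained calibration experiments used for package validation.

Each function simulates data with known ground truth and pushes it through
the corresponding inference path, returning the quantities a user would
inspect to judge calibration: sib-pair kinship means, the mean pair
correlation of complete spatial randomness, dispersal-kernel shape recovery,
full parameter recovery, and type-I error rates of the permutation and
likelihood-ratio tests.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import fsgs, pointpattern, seedfate
from .kernels import DispersalKernel, DispersalParams
from .neighborhood import NeighborhoodData, NeighborhoodFit, fit_neighborhood_model
from .population import MappedIndividual, StudyWindow
from .simulate import (distance_density_design, draw_founder_genotypes,
                       simulate_adults, simulate_allele_frequencies,
                       simulate_offspring_cohort, simulate_seed_fate_experiment)


def sib_pair_kinship(n_pairs: int = 500, shared_parents: int = 2,
                     n_loci: int = 17, alleles: int = 8,
                     seed: int = 0) -> float:
    """Mean Loiselle/Nason kinship over simulated sib pairs.

    ``shared_parents=2`` gives full sibs (expected F = 1/4), ``1`` half sibs
    through a common mother (expected F = 1/8); parents are outbred draws
    from the reference pool.
    """
    rng = np.random.default_rng(seed)
    afreq = simulate_allele_frequencies(n_loci, alleles, seed=rng)
    loci = afreq.loci
    al = {l: afreq.alleles(l) for l in loci}
    p = {l: afreq.freq_array(l) for l in loci}

    def parent():
        return {l: rng.choice(al[l], 2, p=p[l]) for l in loci}

    def child(mo, fa):
        return {l: (rng.choice(mo[l]), rng.choice(fa[l])) for l in loci}

    vals = []
    for _ in range(n_pairs):
        mo, fa = parent(), parent()
        fa2 = fa if shared_parents == 2 else parent()
        a = MappedIndividual("a", 0, 0, genotype=child(mo, fa))
        b = MappedIndividual("b", 1, 0, genotype=child(mo, fa2))
        vals.append(fsgs.pairwise_kinship(a, b, afreq)[0])
    return float(np.mean(vals))


def csr_mean_pcf(n_patterns: int = 50, expected_points: int = 500,
                 side: float = 2000.0, r_min: float = 10.0,
                 r_max: float = 100.0, sigma: float = 250.0,
                 seed: int = 0) -> float:
    """Mean inhomogeneous g(r) over r in [r_min, r_max] across homogeneous
    Poisson patterns (the complete-spatial-randomness reference, g = 1)."""
    rng = np.random.default_rng(seed)
    window = StudyWindow.rectangle(side, side)
    grid = np.linspace(r_min, r_max, 37)
    means = []
    for _ in range(n_patterns):
        n = rng.poisson(expected_points)
        pts = window.sample_uniform(n, rng)
        means.append(pointpattern.pcf_inhom(pts, window, r_grid=grid,
                                            sigma=sigma).g.mean())
    return float(np.mean(means))


def _standard_site(seed: int, n_adults: int = 100, side: float = 2000.0):
    rng = np.random.default_rng(seed)
    window = StudyWindow.rectangle(side, side)
    afreq = simulate_allele_frequencies(17, 8, seed=rng)
    adults = draw_founder_genotypes(
        simulate_adults(window, n_adults / window.area, seed=rng), afreq,
        seed=rng)
    return window, afreq, adults


def kernel_shape_recovery(kind: str, n_offspring: int = 300,
                          n_adults: int = 100, seed: int = 0,
                          n_starts: int = 4) -> NeighborhoodFit:
    """Fit the neighborhood model to offspring simulated under a known radial
    law with no immigration or selfing.

    ``kind='gaussian'``: 2-D isotropic normal displacements, sd 300 m per
    axis (shape exponent b = 2, mean distance 300*sqrt(pi/2)).
    ``kind='exponential'``: location density ~ exp(-d/a) with a = 200 m
    (b = 1, mean distance 2a = 400 m).
    """
    if kind == "gaussian":
        true_seed = DispersalKernel(300.0 * np.sqrt(np.pi / 2), 2.0)
    elif kind == "exponential":
        true_seed = DispersalKernel(400.0, 1.0)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    window, afreq, adults = _standard_site(seed, n_adults)
    truth = DispersalParams(seed=true_seed, pollen=DispersalKernel(300.0, 1.0))
    off, _ = simulate_offspring_cohort(adults, truth, n_offspring, window,
                                       afreq, seed=seed + 1)
    data = NeighborhoodData(off, adults, afreq)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_neighborhood_model(
            data, free=("delta_s", "b_s", "delta_p", "b_p"),
            n_starts=n_starts, seed=seed + 2)


RECOVERY_TRUTH = DispersalParams(s_o=0.1, m_p=0.15, m_s=0.3,
                                 seed=DispersalKernel(500.0, 1.0),
                                 pollen=DispersalKernel(300.0, 1.0))


def parameter_recovery(n_replicates: int = 10, n_offspring: int = 300,
                       n_adults: int = 100, seed: int = 0,
                       n_starts: int = 4) -> dict[str, np.ndarray]:
    """Replicate fits of the full mixture model to data with known parameters.

    Returns the per-replicate estimates of s_o, m_p, m_s, delta_s and
    delta_p alongside the generating truth.
    """
    out = {k: [] for k in ("s_o", "m_p", "m_s", "delta_s", "delta_p")}
    for r in range(n_replicates):
        base = seed + 137 * r
        window, afreq, adults = _standard_site(base, n_adults)
        off, _ = simulate_offspring_cohort(adults, RECOVERY_TRUTH, n_offspring,
                                           window, afreq, seed=base + 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_neighborhood_model(NeighborhoodData(off, adults, afreq),
                                         n_starts=n_starts, seed=base + 2)
        out["s_o"].append(fit.params.s_o)
        out["m_p"].append(fit.params.m_p)
        out["m_s"].append(fit.params.m_s)
        out["delta_s"].append(fit.params.seed.delta)
        out["delta_p"].append(fit.params.pollen.delta)
    return {k: np.array(v) for k, v in out.items()}


def fsgs_type_i_error(n_replicates: int = 1000, n_individuals: int = 60,
                      side: float = 600.0, n_perm: int = 199,
                      alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of the Sp permutation test on structure-free data."""
    rng = np.random.default_rng(seed)
    window = StudyWindow.rectangle(side, side)
    afreq = simulate_allele_frequencies(17, 8, seed=rng)
    hits = 0
    for _ in range(n_replicates):
        pop = draw_founder_genotypes(
            simulate_adults(window, n_individuals / window.area, seed=rng),
            afreq, seed=rng)
        res = fsgs.permutation_test_fsgs(pop, afreq, n_perm=n_perm,
                                         alpha=alpha, seed=rng,
                                         bin_edges=(0, 30, 100, 200, 400, 850))
        hits += res.p_sp <= alpha
    return hits / n_replicates


def lrt_type_i_error(n_replicates: int = 1000, alpha: float = 0.05,
                     seed: int = 0) -> float:
    """Rejection rate of the LRT for a null fixed effect (hunting) on data
    simulated without any hunting effect."""
    design = distance_density_design({"low": 4, "high": 4})
    hits = 0
    for r in range(n_replicates):
        recs = simulate_seed_fate_experiment(design, {"intercept": 0.2},
                                             seed=seed + r)
        small = seedfate.fit_logistic(recs, ["distance"])
        big = seedfate.fit_logistic(recs, ["distance", "hunting"])
        _, _, p = seedfate.likelihood_ratio_test(small, big)
        hits += p <= alpha
    return hits / n_replicates
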