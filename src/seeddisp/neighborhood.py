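"""Neighborhood-model maximum likelihood for seed and pollen dispersal.

Each sampled offspring is modelled as a mixture over parentage histories:
seed immigration (mother outside the candidate set, probability ``m_s``) or a
candidate mother weighted by the seed kernel; given the mother, the father is
the mother herself (selfing, ``s_o``), background pollen (``m_p``) or a
candidate male weighted by the pollen kernel.  Genotype likelihoods are
Mendelian with a per-locus mistyping layer (with probability ``e_l`` the
observed genotype is an independent Hardy-Weinberg draw).  Kernel scale and
shape, immigration, and selfing are estimated jointly by multi-start
maximum likelihood; parentage is then assigned from the fitted posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

from .kernels import DispersalKernel, DispersalParams
from .population import MISSING, AlleleFrequencyTable, Population, as_population

BACKGROUND = "BACKGROUND"

FREE_DEFAULT = ("s_o", "m_p", "m_s", "delta_s", "b_s", "delta_p", "b_p")


def kernel_density(distance, angle=0.0, delta=300.0, b=1.0, kappa=0.0,
                   axis=0.0) -> np.ndarray:
    """Exponential power-von Mises planar density at (distance, angle)."""
    return DispersalKernel(delta, b, kappa, axis).density(distance, angle)


# ---------------------------------------------------------------------------
# single-locus transition probability (reference implementation)


def _gamete_probs(genotype, alleles: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Probability of transmitting each allele; HWE frequencies if missing."""
    if genotype is None:
        return p
    a, b = genotype
    if a == MISSING or b == MISSING:
        return p
    return 0.5 * ((alleles == a).astype(float) + (alleles == b))


def transition_probability(offspring_genotype, mother_genotype, father_genotype,
                           alleles, freqs, e: float = 0.0) -> float:
    """P(observed offspring single-locus genotype | mother, father).

    ``father_genotype`` may be the string BACKGROUND (gamete drawn from the
    reference frequencies).  The mistyping layer replaces the true genotype by
    a random HWE genotype with probability ``e``.  Missing offspring data
    integrate to 1.
    """
    alleles = np.asarray(alleles)
    p = np.asarray(freqs, float)
    if offspring_genotype is None:
        return 1.0
    a, b = offspring_genotype
    if a == MISSING or b == MISSING:
        return 1.0
    pm = _gamete_probs(mother_genotype, alleles, p)
    if isinstance(father_genotype, str) and father_genotype == BACKGROUND:
        pf = p
    else:
        pf = _gamete_probs(father_genotype, alleles, p)
    ia, ib = int(np.where(alleles == a)[0][0]), int(np.where(alleles == b)[0][0])
    mendel = pm[ia] * pf[ib] + (pm[ib] * pf[ia] if a != b else 0.0)
    hwe = p[ia] ** 2 if a == b else 2 * p[ia] * p[ib]
    return float((1 - e) * mendel + e * hwe)


# ---------------------------------------------------------------------------
# dataset with precomputed genotype tables


class NeighborhoodData:
    """Offspring + candidate parents with cached transition-probability tables.

    Candidate mothers are females plus unknown-sex adults; candidate fathers
    are males plus unknown-sex adults.  ``known_mothers`` maps offspring id to
    a candidate mother id for seeds collected under identified trees; those
    offspring contribute a paternity-only likelihood.
    """

    def __init__(self, offspring, candidates, afreq: AlleleFrequencyTable,
                 known_mothers: dict[str, str] | None = None,
                 allow_self_pairing: bool = False):
        off = as_population(offspring)
        cand = as_population(candidates)
        clash = set(off.ids) & set(cand.ids)
        if clash:
            warnings.warn(f"{len(clash)} offspring also appear as candidates; "
                          "excluded from the offspring set", stacklevel=2)
            off = off.subset([i for i, x in enumerate(off.ids) if x not in clash])
        self.offspring = off
        self.mothers = cand.subset(np.isin(cand.sex, ["female", "unknown"]))
        self.fathers = cand.subset(np.isin(cand.sex, ["male", "unknown"]))
        if len(self.mothers) == 0:
            raise ValueError("no candidate mothers")
        if len(self.fathers) == 0:
            raise ValueError("no candidate fathers")
        self.afreq = afreq
        self.loci = [l for l in afreq.loci if l in off.loci]

        self.d_seed = np.linalg.norm(off.xy[:, None, :] - self.mothers.xy[None, :, :],
                                     axis=2)
        self.d_pollen = np.linalg.norm(self.mothers.xy[:, None, :]
                                       - self.fathers.xy[None, :, :], axis=2)
        # forbid the same individual acting as its own mate outside the selfing term
        self.pollen_mask = np.ones_like(self.d_pollen, bool)
        if not allow_self_pairing:
            for j, mid in enumerate(self.mothers.ids):
                for k, fid in enumerate(self.fathers.ids):
                    if mid == fid:
                        self.pollen_mask[j, k] = False

        self.known_idx = {}
        for oid, mid in (known_mothers or {}).items():
            if oid in off.ids and mid in self.mothers.ids:
                self.known_idx[off.ids.index(oid)] = self.mothers.ids.index(mid)

        self._blocks = self._genotype_blocks()
        self._cache_key = None
        self._cache = None

    # -- per-locus building blocks ------------------------------------------

    def _genotype_blocks(self):
        blocks = []
        for locus in self.loci:
            alleles = self.afreq.alleles(locus)
            p = self.afreq.freq_array(locus)
            li = self.offspring.loci.index(locus)
            og = self.offspring.genotypes[:, li, :]
            omiss = (og == MISSING).any(axis=1)
            amap = {int(a): i for i, a in enumerate(alleles)}
            ia = np.array([amap.get(int(a), -1) for a in og[:, 0]])
            ib = np.array([amap.get(int(b), -1) for b in og[:, 1]])
            omiss |= (ia < 0) | (ib < 0)
            ia, ib = np.where(omiss, 0, ia), np.where(omiss, 0, ib)

            def gametes(pop):
                lj = pop.loci.index(locus)
                g = pop.genotypes[:, lj, :]
                miss = (g == MISSING).any(axis=1)
                m = 0.5 * ((g[:, 0, None] == alleles[None, :]).astype(float)
                           + (g[:, 1, None] == alleles[None, :]))
                return np.where(miss[:, None], p[None, :], m)

            blocks.append(dict(p=p, ia=ia, ib=ib, het=(ia != ib) & ~omiss,
                               miss=omiss, Mm=gametes(self.mothers),
                               Mf=gametes(self.fathers)))
        return blocks

    def _locus_factors(self, blk, e: float):
        """(T_pair, T_self, T_bgf, P_hwe) for one locus at mistyping rate e."""
        p, ia, ib, het, miss = blk["p"], blk["ia"], blk["ib"], blk["het"], blk["miss"]
        Mm, Mf = blk["Mm"], blk["Mf"]
        A1, A2 = Mm[:, ia].T, Mm[:, ib].T          # (n_off, n_m)
        B1, B2 = Mf[:, ib].T, Mf[:, ia].T          # (n_off, n_f)
        hetf = het.astype(float)
        pair = A1[:, :, None] * B1[:, None, :] \
            + hetf[:, None, None] * (A2[:, :, None] * B2[:, None, :])
        selfed = A1 * A2 * (1.0 + hetf)[:, None]
        bgf = A1 * p[ib][:, None] + hetf[:, None] * A2 * p[ia][:, None]
        hwe = np.where(het, 2 * p[ia] * p[ib], p[ia] ** 2)
        if e > 0:
            pair = (1 - e) * pair + e * hwe[:, None, None]
            selfed = (1 - e) * selfed + e * hwe[:, None]
            bgf = (1 - e) * bgf + e * hwe[:, None]
        pair[miss] = 1.0
        selfed[miss] = 1.0
        bgf[miss] = 1.0
        hwe = np.where(miss, 1.0, hwe)
        return pair, selfed, bgf, hwe

    def transition_tables(self, e_l: dict[str, float] | None):
        """Multilocus products T_pair (o,j,k), T_self (o,j), T_bgf (o,j),
        P_bg (o), cached per mistyping configuration."""
        e_l = e_l or {}
        key = tuple(float(e_l.get(l, 0.0)) for l in self.loci)
        if key == self._cache_key:
            return self._cache
        n_o, n_m, n_f = len(self.offspring), len(self.mothers), len(self.fathers)
        T_pair = np.ones((n_o, n_m, n_f))
        T_self = np.ones((n_o, n_m))
        T_bgf = np.ones((n_o, n_m))
        P_bg = np.ones(n_o)
        for blk, e in zip(self._blocks, key):
            pair, selfed, bgf, hwe = self._locus_factors(blk, e)
            T_pair *= pair
            T_self *= selfed
            T_bgf *= bgf
            P_bg *= hwe
        self._cache_key, self._cache = key, (T_pair, T_self, T_bgf, P_bg)
        return self._cache


# ---------------------------------------------------------------------------
# likelihood


def _normalized_weights(log_density: np.ndarray, mask: np.ndarray | None = None,
                        axis: int = -1) -> np.ndarray:
    """exp-normalize kernel log densities along an axis, mask-aware."""
    ld = np.array(log_density, float)
    if mask is not None:
        ld[~mask] = -np.inf
    mx = ld.max(axis=axis, keepdims=True)
    mx = np.where(np.isfinite(mx), mx, 0.0)
    w = np.exp(ld - mx)
    tot = w.sum(axis=axis, keepdims=True)
    return np.where(tot > 0, w / np.where(tot > 0, tot, 1.0), 0.0)


def _per_offspring_components(data: NeighborhoodData, params: DispersalParams):
    """Mixture components: (imm (o,), inner (o,j), w_s (o,j), parts dict)."""
    T_pair, T_self, T_bgf, P_bg = data.transition_tables(params.e_l)
    w_s = _normalized_weights(params.seed.log_density(data.d_seed), axis=1)
    w_p = _normalized_weights(params.pollen.log_density(data.d_pollen),
                              mask=data.pollen_mask, axis=1)
    pollen_term = np.einsum("jk,ojk->oj", w_p, T_pair)
    out_rate = 1.0 - params.s_o - params.m_p
    inner = params.s_o * T_self + params.m_p * T_bgf + out_rate * pollen_term
    return P_bg, inner, w_s, w_p


def neighborhood_loglik(data: NeighborhoodData, params: DispersalParams,
                        per_offspring: bool = False):
    """Total log-likelihood of the offspring set under the mixture model."""
    P_bg, inner, w_s, _ = _per_offspring_components(data, params)
    L = params.m_s * P_bg + (1 - params.m_s) * np.einsum("oj,oj->o", w_s, inner)
    for o, j in data.known_idx.items():
        L[o] = inner[o, j]        # known mother: paternity-only likelihood
    bad = L <= 0
    if bad.any():
        warnings.warn("zero likelihood for offspring: "
                      f"{[data.offspring.ids[i] for i in np.flatnonzero(bad)[:10]]}",
                      stacklevel=2)
    with np.errstate(divide="ignore"):
        ll = np.log(L)
    return ll if per_offspring else float(ll.sum())


# ---------------------------------------------------------------------------
# fitting


_LOGIT_BOUND = 12.0


def _logit(p):
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


_TRANSFORMS = {
    "m_s": (_logit, _expit, (-_LOGIT_BOUND, _LOGIT_BOUND)),
    "delta_s": (np.log, np.exp, (np.log(1.0), np.log(1e5))),
    "b_s": (np.log, np.exp, (np.log(0.2), np.log(5.0))),
    "delta_p": (np.log, np.exp, (np.log(1.0), np.log(1e5))),
    "b_p": (np.log, np.exp, (np.log(0.2), np.log(5.0))),
    "kappa_s": (np.log, np.exp, (np.log(1e-3), np.log(50.0))),
    "kappa_p": (np.log, np.exp, (np.log(1e-3), np.log(50.0))),
}


def _params_to_dict(params: DispersalParams) -> dict[str, float]:
    return dict(s_o=params.s_o, m_p=params.m_p, m_s=params.m_s,
                delta_s=params.seed.delta, b_s=params.seed.b,
                kappa_s=params.seed.kappa,
                delta_p=params.pollen.delta, b_p=params.pollen.b,
                kappa_p=params.pollen.kappa)


def _dict_to_params(d: dict[str, float], e_l: dict[str, float]) -> DispersalParams:
    return DispersalParams(
        s_o=d["s_o"], m_p=d["m_p"], m_s=d["m_s"],
        seed=DispersalKernel(d["delta_s"], d["b_s"], d["kappa_s"]),
        pollen=DispersalKernel(d["delta_p"], d["b_p"], d["kappa_p"]), e_l=e_l)


def _pack(d: dict[str, float], free: list[str]) -> np.ndarray:
    """Parameter dict -> unconstrained vector.  The (s_o, m_p) simplex uses
    two-logit stick-breaking: v1 = logit(s_o), v2 = logit(m_p / (1 - s_o))."""
    x = []
    for name in free:
        if name == "s_o":
            x.append(_logit(d["s_o"]))
        elif name == "m_p":
            x.append(_logit(d["m_p"] / max(1 - d["s_o"], 1e-9)))
        else:
            x.append(_TRANSFORMS[name][0](d[name]))
    return np.array(x, float)


def _unpack(x: np.ndarray, free: list[str], base: dict[str, float]) -> dict[str, float]:
    d = dict(base)
    for name, v in zip(free, x):
        if name == "s_o":
            d["s_o"] = _expit(v)
        elif name == "m_p":
            d["_m_p_frac"] = _expit(v)
        else:
            d[name] = _TRANSFORMS[name][1](v)
    if "_m_p_frac" in d:
        d["m_p"] = d.pop("_m_p_frac") * (1 - d["s_o"])
    return d


@dataclass
class NeighborhoodFit:
    """Fitted neighborhood model with convergence diagnostics."""

    params: DispersalParams
    loglik: float
    converged: bool
    data: NeighborhoodData
    free: list[str]
    starts: list = field(default_factory=list)
    boundary_flags: list = field(default_factory=list)


def fit_neighborhood_model(data: NeighborhoodData,
                           init: DispersalParams | None = None,
                           free: tuple[str, ...] = FREE_DEFAULT,
                           n_starts: int = 8,
                           seed: int | np.random.Generator = 0) -> NeighborhoodFit:
    """Maximize the neighborhood likelihood over the free parameters.

    Probabilities are optimized on logit scale (the s_o + m_p <= 1 constraint
    through stick-breaking), kernel scales/shapes on log scale, with
    multi-start L-BFGS-B from deterministically perturbed initial points.
    """
    rng = np.random.default_rng(seed)
    free = [f for f in free]
    unknown = set(free) - set(FREE_DEFAULT) - {"kappa_s", "kappa_p"}
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    if init is None:
        scale0 = float(np.median(data.d_seed))
        init = DispersalParams(s_o=0.05, m_p=0.2, m_s=0.2,
                               seed=DispersalKernel(scale0, 1.0),
                               pollen=DispersalKernel(scale0, 1.0))
    base = _params_to_dict(init)
    for k in ("kappa_s", "kappa_p"):
        if k in free and base[k] == 0:
            base[k] = 0.1
    e_l = dict(init.e_l)

    def objective(x):
        d = _unpack(x, free, base)
        try:
            params = _dict_to_params(d, e_l)
        except ValueError:
            return 1e12
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ll = neighborhood_loglik(data, params)
        return 1e12 if not np.isfinite(ll) else -ll

    bounds = []
    for name in free:
        if name in ("s_o", "m_p", "m_s"):
            bounds.append((-_LOGIT_BOUND, _LOGIT_BOUND))
        else:
            bounds.append(_TRANSFORMS[name][2])

    x0 = _pack(base, free)
    starts = [x0] + [x0 + rng.normal(0, 1.0, len(x0)) for _ in range(n_starts - 1)]
    starts = [np.clip(s, [b[0] for b in bounds], [b[1] for b in bounds])
              for s in starts]

    results = []
    for s in starts:
        res = optimize.minimize(objective, s, method="L-BFGS-B", bounds=bounds)
        results.append(res)
    ok = [r for r in results if np.isfinite(r.fun) and r.fun < 1e11]
    if not ok:
        raise RuntimeError("neighborhood fit failed to converge from any start; "
                           f"diagnostics: {[r.message for r in results]}")
    best = min(ok, key=lambda r: r.fun)
    d = _unpack(best.x, free, base)
    params = _dict_to_params(d, e_l)

    flags = []
    for name, v, (lo, hi) in zip(free, best.x, bounds):
        if v - lo < 1e-3 * (hi - lo) or hi - v < 1e-3 * (hi - lo):
            flags.append(name)
    return NeighborhoodFit(params=params, loglik=-float(best.fun),
                           converged=bool(best.success), data=data, free=free,
                           starts=[(r.x, -float(r.fun), bool(r.success))
                                   for r in results],
                           boundary_flags=flags)


def estimate_error_rates(data: NeighborhoodData, params: DispersalParams,
                         e_grid: np.ndarray | None = None,
                         n_cycles: int = 2) -> dict[str, float]:
    """Per-locus mistyping rates by cyclic profile likelihood.

    Holding the dispersal parameters fixed, each locus's rate is profiled on
    a grid while the other loci keep their current rates; cycles repeat until
    stable.  Supports the borrowed-rate workflow (estimate on a reference
    dataset, fix elsewhere).
    """
    if e_grid is None:
        e_grid = np.concatenate([[0.0], np.geomspace(1e-3, 0.3, 12)])
    e_l = {l: float(params.e_l.get(l, 0.0)) for l in data.loci}
    for _ in range(n_cycles):
        for locus in data.loci:
            best_e, best_ll = e_l[locus], -np.inf
            for e in e_grid:
                trial = dict(e_l)
                trial[locus] = float(e)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ll = neighborhood_loglik(data, params.with_error_rates(trial))
                if ll > best_ll:
                    best_ll, best_e = ll, float(e)
            e_l[locus] = best_e
    return e_l


# ---------------------------------------------------------------------------
# parentage assignment


def assign_parentage(fit: NeighborhoodFit, threshold: float = 0.5,
                     near_distance: float = 20.0) -> pd.DataFrame:
    """Most probable mother and father per offspring with posterior support.

    Category follows the three-way classification used for sapling cohorts:
    'not_dispersed' (assigned mother within ``near_distance`` m),
    'dispersed_within_plot' (assigned mother farther away), and
    'dispersed_from_outside' (no mother reaching the posterior threshold).
    """
    data, params = fit.data, fit.params
    P_bg, inner, w_s, w_p = _per_offspring_components(data, params)
    T_pair, T_self, T_bgf, _ = data.transition_tables(params.e_l)
    out_rate = 1.0 - params.s_o - params.m_p

    rows = []
    for o, oid in enumerate(data.offspring.ids):
        if o in data.known_idx:
            j0 = data.known_idx[o]
            mother_post = np.zeros(len(data.mothers))
            mother_post[j0] = 1.0
            imm = 0.0
            L = inner[o, j0]
            comp_self = params.s_o * T_self[o, j0]
            comp_bg = params.m_p * T_bgf[o, j0]
            father_post = out_rate * w_p[j0] * T_pair[o, j0]
        else:
            comp_m = (1 - params.m_s) * w_s[o] * inner[o]
            imm = params.m_s * P_bg[o]
            L = imm + comp_m.sum()
            mother_post = comp_m
            comp_self = (1 - params.m_s) * np.sum(w_s[o] * params.s_o * T_self[o])
            comp_bg = (1 - params.m_s) * np.sum(w_s[o] * params.m_p * T_bgf[o])
            father_post = (1 - params.m_s) * out_rate * np.einsum(
                "j,jk,jk->k", w_s[o], w_p, T_pair[o])
        if L <= 0:
            rows.append(dict(offspring=oid, mother=None, mother_prob=np.nan,
                             father=None, father_prob=np.nan, distance=np.nan,
                             category="unresolved"))
            continue
        mother_post = mother_post / L
        p_imm_mother = imm / L
        j_best = int(np.argmax(mother_post))
        m_prob = float(mother_post[j_best])

        father_marg = father_post / L
        p_self = float(np.sum(comp_self) / L)
        p_bgf = float(np.sum(comp_bg) / L) + p_imm_mother
        k_best = int(np.argmax(father_marg))
        cand = {"self": p_self, "background": p_bgf,
                "male": float(father_marg[k_best])}
        f_label = max(cand, key=cand.get)

        if m_prob >= threshold:
            mother = data.mothers.ids[j_best]
            dist = float(data.d_seed[o, j_best])
            category = ("not_dispersed" if dist < near_distance
                        else "dispersed_within_plot")
        else:
            mother, dist, category = None, np.nan, "dispersed_from_outside"
        if f_label == "male" and cand["male"] >= threshold:
            father, f_prob = data.fathers.ids[k_best], cand["male"]
        elif f_label == "self" and p_self >= threshold:
            father, f_prob = mother or "SELF", p_self
        else:
            father, f_prob = None, float(max(cand.values()))
        rows.append(dict(offspring=oid, mother=mother, mother_prob=m_prob,
                         father=father, father_prob=f_prob,
                         distance=dist, category=category))
    return pd.DataFrame(rows)


def mean_dispersal_distance(assignments: pd.DataFrame,
                            alpha: float = 0.05) -> tuple[float, float, float]:
    """Mean assigned mother-offspring distance with a normal-theory CI."""
    d = assignments["distance"].dropna().to_numpy(float)
    if len(d) == 0:
        return np.nan, np.nan, np.nan
    m = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(len(d))) if len(d) > 1 else np.nan
    z = stats.norm.ppf(1 - alpha / 2)
    return m, m - z * se, m + z * se


def immigration_summary(assignments: pd.DataFrame, alpha: float = 0.05
                        ) -> pd.DataFrame:
    """Seed and pollen immigration proportions with Wilson intervals."""
    rows = []
    n = len(assignments)
    seed_k = int((assignments["category"] == "dispersed_from_outside").sum())
    pollen_k = int(assignments["father"].isna().sum())
    for label, k in (("seed", seed_k), ("pollen", pollen_k)):
        lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson") \
            if n else (np.nan, np.nan)
        rows.append(dict(type=label, n=n, k=k,
                         proportion=k / n if n else np.nan, ci_low=lo, ci_high=hi))
    return pd.DataFrame(rows)
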