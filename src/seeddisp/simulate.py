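"""Synthetic populations with known spatial, genetic and experimental structure.

Generates spatially explicit dioecious tree populations (mapped adults with
microsatellite genotypes), offspring cohorts produced under an explicit
seed/pollen dispersal model with known parentage, genotyping error, and
factorial seed-fate experiments — the ground truth against which the
inference modules are validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .kernels import DispersalParams
from .population import (MISSING, AlleleFrequencyTable, DegenerateWindowError,
                         MappedIndividual, Population, StudyWindow, as_population,
                         cohort_from_dbh)

IMMIGRANT = "IMMIGRANT"
SELF = "SELF"


@dataclass(frozen=True)
class TruthRecord:
    """Realized parentage of one simulated offspring."""

    offspring_id: str
    mother_id: str          # adult id or IMMIGRANT
    father_id: str          # adult id, IMMIGRANT (background pollen) or SELF
    distance: float         # realized mother-offspring distance, m (nan if immigrant)


@dataclass(frozen=True)
class ThomasClustering:
    """Thomas cluster process: Poisson parents, Gaussian-scattered offspring."""

    parent_intensity: float     # parents per m^2
    cluster_sd: float           # scatter sd per axis, m
    mean_per_cluster: float     # mean offspring per parent


# ---------------------------------------------------------------------------
# adults


def simulate_adults(window: StudyWindow, intensity: float,
                    clustering: ThomasClustering | None = None,
                    female_fraction: float = 0.5,
                    dbh_median: float = 25.0, dbh_sigma: float = 0.5,
                    seed: int | np.random.Generator = 0) -> list[MappedIndividual]:
    """Simulate mapped adult trees in a window.

    With ``clustering=None`` the positions are a homogeneous Poisson process
    of the given intensity (trees per m^2); otherwise a Thomas cluster process
    with total intensity matching ``intensity``.  Sexes are i.i.d. Bernoulli
    draws (the species is dioecious); dbh is log-normal with the configured
    median and log-sd, resampled to stay above the adult threshold.
    """
    if intensity <= 0:
        raise ValueError("intensity must be > 0")
    if not 0 < female_fraction < 1:
        raise ValueError("female_fraction must be in (0, 1)")
    if window.area <= 0:
        raise DegenerateWindowError("window has no usable area")
    rng = np.random.default_rng(seed)

    if clustering is None:
        n = rng.poisson(intensity * window.area)
        xy = window.sample_uniform(n, rng)
    else:
        xy = _thomas_points(window, intensity, clustering, rng)
        n = len(xy)

    sex = np.where(rng.random(n) < female_fraction, "female", "male")
    dbh = _lognormal_dbh(n, dbh_median, dbh_sigma, lower=10.0, rng=rng)
    return [MappedIndividual(f"A{i:04d}", float(xy[i, 0]), float(xy[i, 1]),
                             cohort="adult", sex=str(sex[i]), dbh=float(dbh[i]))
            for i in range(n)]


def _lognormal_dbh(n: int, median: float, sigma: float, lower: float,
                   rng: np.random.Generator) -> np.ndarray:
    out = np.exp(np.log(median) + sigma * rng.standard_normal(n))
    bad = out < lower
    while bad.any():
        out[bad] = np.exp(np.log(median) + sigma * rng.standard_normal(bad.sum()))
        bad = out < lower
    return out


def _thomas_points(window: StudyWindow, intensity: float, cl: ThomasClustering,
                   rng: np.random.Generator) -> np.ndarray:
    xmin, ymin, xmax, ymax = window.bounds
    pad = 4 * cl.cluster_sd   # parents outside contribute edge clusters
    n_par = rng.poisson(cl.parent_intensity * (xmax - xmin + 2 * pad) * (ymax - ymin + 2 * pad))
    px = rng.uniform(xmin - pad, xmax + pad, n_par)
    py = rng.uniform(ymin - pad, ymax + pad, n_par)
    # rescale mean offspring so the realized in-window intensity matches `intensity`
    mean_off = intensity / cl.parent_intensity
    counts = rng.poisson(mean_off, n_par)
    cx = np.repeat(px, counts) + cl.cluster_sd * rng.standard_normal(counts.sum())
    cy = np.repeat(py, counts) + cl.cluster_sd * rng.standard_normal(counts.sum())
    keep = window.contains(cx, cy)
    return np.column_stack([cx[keep], cy[keep]])


# ---------------------------------------------------------------------------
# genotypes


def simulate_allele_frequencies(n_loci: int = 17, alleles_per_locus: int = 8,
                                concentration: float = 1.0,
                                seed: int | np.random.Generator = 0) -> AlleleFrequencyTable:
    """Reference allele frequencies from a symmetric Dirichlet per locus."""
    if n_loci < 1 or alleles_per_locus < 2:
        raise ValueError("need n_loci >= 1 and alleles_per_locus >= 2")
    if concentration <= 0:
        raise ValueError("Dirichlet concentration must be > 0")
    rng = np.random.default_rng(seed)
    freqs, n_genes = {}, {}
    for l in range(n_loci):
        locus = f"L{l + 1:02d}"
        p = rng.dirichlet(np.full(alleles_per_locus, concentration))
        # keep all alleles representable: floor tiny frequencies
        p = np.clip(p, 1e-6, None)
        p /= p.sum()
        freqs[locus] = {a + 1: float(p[a]) for a in range(alleles_per_locus)}
        n_genes[locus] = 0
    return AlleleFrequencyTable(freqs, n_genes)


def _draw_genotype_array(n: int, afreq: AlleleFrequencyTable,
                         rng: np.random.Generator) -> np.ndarray:
    loci = afreq.loci
    geno = np.empty((n, len(loci), 2), int)
    for l, locus in enumerate(loci):
        alleles = afreq.alleles(locus)
        p = afreq.freq_array(locus)
        geno[:, l, :] = rng.choice(alleles, size=(n, 2), p=p)
    return geno


def draw_founder_genotypes(adults, afreq: AlleleFrequencyTable,
                           seed: int | np.random.Generator = 0,
                           missing_rate: float = 0.0) -> Population:
    """Assign Hardy-Weinberg genotypes (alleles i.i.d. from ``afreq``) to adults."""
    pop = as_population(adults)
    rng = np.random.default_rng(seed)
    out = Population(pop.ids, pop.xy, pop.cohort, pop.sex, pop.dbh, afreq.loci,
                     _draw_genotype_array(len(pop), afreq, rng))
    if missing_rate > 0:
        drop = rng.random((len(out), out.n_loci)) < missing_rate
        out.genotypes[drop] = MISSING
    return out


# ---------------------------------------------------------------------------
# offspring cohorts


def simulate_offspring_cohort(adults, params: DispersalParams, n_offspring: int,
                              window: StudyWindow, afreq: AlleleFrequencyTable,
                              seed: int | np.random.Generator = 0,
                              cohort: str = "small_sapling",
                              id_prefix: str = "O") -> tuple[Population, list[TruthRecord]]:
    """Simulate an offspring cohort under the neighborhood dispersal model.

    Each offspring is a seed immigrant with probability ``m_s`` (genotype from
    the background pool, position uniform in the window).  Otherwise a mother
    is drawn uniformly among female adults (equal fecundity), the offspring
    position is the mother's position plus a seed-kernel displacement (redrawn
    until inside the window), and the father is the mother herself (selfing,
    probability ``s_o``), a background pollen gamete (``m_p``), or a male
    chosen with probability proportional to the pollen-kernel density at his
    distance from the mother.  Inheritance is Mendelian per locus.
    """
    pop = as_population(adults)
    rng = np.random.default_rng(seed)
    mothers_idx = np.flatnonzero(pop.sex == "female")
    fathers_idx = np.flatnonzero(pop.sex == "male")
    if params.m_s < 1.0:
        if len(mothers_idx) == 0:
            raise ValueError("no candidate mothers (female adults) available")
        if len(fathers_idx) == 0 and params.s_o + params.m_p < 1.0:
            raise ValueError("no candidate fathers (male adults) available")

    loci = afreq.loci
    if set(loci) - set(pop.loci):
        raise ValueError("adults are not genotyped at the reference loci")
    locus_pos = [pop.loci.index(l) for l in loci]
    adult_geno = pop.genotypes[:, locus_pos, :]

    n = int(n_offspring)
    geno = np.empty((n, len(loci), 2), int)
    xy = np.empty((n, 2))
    truth: list[TruthRecord] = []

    # pollen competition weights per mother (rows) over candidate fathers
    if len(fathers_idx) and len(mothers_idx):
        dmat = np.linalg.norm(pop.xy[mothers_idx][:, None, :]
                              - pop.xy[fathers_idx][None, :, :], axis=2)
        wp = params.pollen.density(dmat)
        row_sums = wp.sum(axis=1, keepdims=True)
        wp = np.where(row_sums > 0, wp / row_sums, 1.0 / max(len(fathers_idx), 1))
    else:
        wp = None

    for i in range(n):
        oid = f"{id_prefix}{i:04d}"
        if rng.random() < params.m_s:
            xy[i] = window.sample_uniform(1, rng)[0]
            geno[i] = _draw_genotype_array(1, afreq, rng)[0]
            truth.append(TruthRecord(oid, IMMIGRANT, IMMIGRANT, float("nan")))
            continue
        mi = mothers_idx[rng.integers(len(mothers_idx))]
        pos = _displace_into_window(pop.xy[mi], params.seed, window, rng)
        xy[i] = pos
        dist = float(np.hypot(*(pos - pop.xy[mi])))
        u = rng.random()
        if u < params.s_o:
            father, fid = mi, SELF
        elif u < params.s_o + params.m_p:
            father, fid = None, IMMIGRANT
        else:
            row = wp[list(mothers_idx).index(mi)]
            father = fathers_idx[rng.choice(len(fathers_idx), p=row)]
            fid = pop.ids[father]
        mat_gam = adult_geno[mi, np.arange(len(loci)), rng.integers(0, 2, len(loci))]
        if father is None:
            pat_gam = np.array([rng.choice(afreq.alleles(l), p=afreq.freq_array(l))
                                for l in loci])
        else:
            pat_gam = adult_geno[father, np.arange(len(loci)), rng.integers(0, 2, len(loci))]
        geno[i] = np.column_stack([mat_gam, pat_gam])
        truth.append(TruthRecord(oid, pop.ids[mi], fid, dist))

    dbh = rng.uniform(0.5, 4.9, n) if cohort == "small_sapling" else rng.uniform(5.0, 9.9, n)
    off = Population([t.offspring_id for t in truth], xy,
                     [cohort] * n, ["unknown"] * n, dbh, loci, geno)
    assert all(cohort_from_dbh(d) == cohort for d in off.dbh)
    return off, truth


def _displace_into_window(origin: np.ndarray, kernel, window: StudyWindow,
                          rng: np.random.Generator, max_tries: int = 10000) -> np.ndarray:
    """Origin plus a kernel displacement, redrawn until inside the window."""
    for _ in range(max_tries):
        pos = origin + kernel.sample_displacements(1, rng)[0]
        if window.contains(np.array([pos[0]]), np.array([pos[1]]))[0]:
            return pos
    raise RuntimeError("could not place offspring inside window (kernel scale "
                       "much larger than window?)")


def apply_genotyping_error(individuals, error_rates: dict[str, float],
                           afreq: AlleleFrequencyTable,
                           seed: int | np.random.Generator = 0) -> Population:
    """Perturb genotypes with per-locus mistyping.

    Independently for each recorded allele copy, with probability ``e_l`` the
    allele is replaced by a random draw from that locus's reference
    frequencies.  Missing genotypes stay missing.  The input is not modified.
    """
    pop = as_population(individuals)
    if set(error_rates) != set(pop.loci):
        raise ValueError("error_rates loci do not match population loci")
    for locus, e in error_rates.items():
        if not 0.0 <= e <= 1.0:
            raise ValueError(f"error rate at {locus} outside [0, 1]")
    rng = np.random.default_rng(seed)
    geno = pop.genotypes.copy()
    for l, locus in enumerate(pop.loci):
        e = error_rates[locus]
        if e == 0:
            continue
        alleles, p = afreq.alleles(locus), afreq.freq_array(locus)
        hit = (rng.random((len(pop), 2)) < e) & (geno[:, l, :] != MISSING)
        geno[:, l, :][hit] = rng.choice(alleles, size=int(hit.sum()), p=p)
    return Population(pop.ids, pop.xy, pop.cohort, pop.sex, pop.dbh, pop.loci, geno)


def truth_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in truth])


# ---------------------------------------------------------------------------
# seed-fate experiments


@dataclass(frozen=True)
class SeedFateRecord:
    """One experimental seed or seedling and its recorded fate."""

    unit: str               # adult tree or station id (random-effect group)
    treatment: str          # fruit | naked | dung | dung_gut
    caged: bool
    distance: float         # m to the focal adult (0 for substrate stations)
    density: int            # seeds per subplot
    hunting: str            # low | high
    fate: str               # intact/removed/damaged/rotten/germinated/established/dead


def distance_density_design(units: dict[str, int] = {"low": 14, "high": 25},
                            distances: Sequence[float] = (2.0, 20.0, 50.0),
                            densities: Sequence[int] = (2, 25)) -> pd.DataFrame:
    """Seed-sowing design: per adult tree, two opposite transects (one per
    density) with one subplot at each distance; one row per seed."""
    rows = []
    for hunting, n_units in units.items():
        for u in range(n_units):
            unit = f"{hunting}_T{u:02d}"
            for dist in distances:
                for dens in densities:
                    for _ in range(dens):
                        rows.append(dict(unit=unit, treatment="naked", caged=False,
                                         distance=float(dist), density=int(dens),
                                         hunting=hunting))
    return pd.DataFrame(rows)


def seed_environment_design(replicates: int = 60, seeds_per_group: int = 5,
                            treatments: Sequence[str] = ("fruit", "naked", "dung"),
                            caged: bool = False,
                            include_gut: bool = False) -> pd.DataFrame:
    """Seed-substrate design: stations each holding one group per treatment;
    the gut-passage treatment exists only inside exclusion cages."""
    rows = []
    tlist = list(treatments) + (["dung_gut"] if include_gut and caged else [])
    for r in range(replicates):
        unit = f"S{r:03d}"
        for tr in tlist:
            for _ in range(seeds_per_group):
                rows.append(dict(unit=unit, treatment=tr, caged=caged,
                                 distance=0.0, density=seeds_per_group, hunting="low"))
    return pd.DataFrame(rows)


class EffectSpecificationError(ValueError):
    """An effect term does not match any design covariate."""


def _term_column(design: pd.DataFrame, factor: str) -> np.ndarray:
    """One multiplicative factor of an effect term: ``col`` (numeric) or
    ``col[level]`` (categorical indicator)."""
    if factor.endswith("]") and "[" in factor:
        col, level = factor[:-1].split("[", 1)
        if col not in design.columns:
            raise EffectSpecificationError(f"unknown covariate {col!r}")
        return (design[col].astype(str) == level).to_numpy(float)
    if factor in design.columns and pd.api.types.is_numeric_dtype(design[factor]):
        return design[factor].to_numpy(float)
    raise EffectSpecificationError(f"unknown term factor {factor!r}")


def _linear_predictor(design: pd.DataFrame, effects: dict[str, float]) -> np.ndarray:
    eta = np.zeros(len(design))
    for term, coef in effects.items():
        if term == "intercept":
            eta += coef
            continue
        col = np.ones(len(design))
        for factor in term.split(":"):
            col = col * _term_column(design, factor)
        eta += coef * col
    return eta


def simulate_seed_fate_experiment(design: pd.DataFrame, effects: dict[str, float],
                                  unit_sd: float = 0.0,
                                  seed: int | np.random.Generator = 0,
                                  success_fate: str = "germinated",
                                  failure_fate: str = "removed") -> list[SeedFateRecord]:
    """Draw per-seed binary outcomes from a logit-linear model.

    ``effects`` maps term names to logit-scale coefficients: ``"intercept"``,
    a numeric column name (``"distance"``), a categorical indicator
    (``"hunting[high]"``) or a ``:``-separated interaction of such factors
    (``"distance:hunting[high]"``).  Unit-level random intercepts are
    Normal(0, unit_sd^2).
    """
    rng = np.random.default_rng(seed)
    eta = _linear_predictor(design, effects)
    units = design["unit"].astype(str)
    levels = units.unique()
    re = dict(zip(levels, rng.normal(0.0, unit_sd, len(levels))))
    eta = eta + units.map(re).to_numpy(float)
    p = 1.0 / (1.0 + np.exp(-eta))
    success = rng.random(len(design)) < p
    return [SeedFateRecord(unit=str(row.unit), treatment=str(row.treatment),
                           caged=bool(row.caged), distance=float(row.distance),
                           density=int(row.density), hunting=str(row.hunting),
                           fate=success_fate if ok else failure_fate)
            for ok, (_, row) in zip(success, design.iterrows())]


def seed_fate_frame(records: Sequence[SeedFateRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
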