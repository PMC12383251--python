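"""Configuration-driven orchestration of the full synthetic study.

A study config fixes every seed and every analysis setting (distance bins,
intensity bandwidth, simulation and permutation counts, posterior threshold).
``run_study`` simulates one population per hunting regime under its dispersal
parameters, runs demography, point-pattern, FSGS and neighborhood analyses on
each, fits the seed-fate experiments, and writes per-module tables plus a
combined summary and a manifest of seeds and input hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demography, fsgs, io, neighborhood, pointpattern, seedfate
from .kernels import DispersalKernel, DispersalParams
from .population import StudyWindow
from .simulate import (distance_density_design, draw_founder_genotypes,
                       seed_fate_frame, simulate_adults,
                       simulate_allele_frequencies, simulate_offspring_cohort,
                       simulate_seed_fate_experiment, truth_frame)

log = logging.getLogger("seeddisp")


@dataclass
class RegimeConfig:
    """Dispersal regime of one simulated site (all rates per offspring)."""

    name: str = "low_hunting"
    s_o: float = 0.05
    m_p: float = 0.2
    m_s: float = 0.8           # seed immigration: high where elephants roam
    delta_s: float = 1000.0    # mean seed dispersal distance, m
    b_s: float = 1.0
    delta_p: float = 300.0     # mean pollen dispersal distance, m
    b_p: float = 1.0
    n_small_saplings: int | None = None   # override the study-wide counts,
    n_large_saplings: int | None = None   # e.g. a suppressed recruit cohort

    def params(self) -> DispersalParams:
        return DispersalParams(s_o=self.s_o, m_p=self.m_p, m_s=self.m_s,
                               seed=DispersalKernel(self.delta_s, self.b_s),
                               pollen=DispersalKernel(self.delta_p, self.b_p))


@dataclass
class StudyConfig:
    """All knobs of the end-to-end synthetic study (defaults mirror the
    field-study analysis settings)."""

    seed: int = 0
    window_size: float = 2000.0            # square plot side, m
    adult_intensity: float = 2.5e-5        # adults per m^2 (~100 per 4 km^2)
    n_loci: int = 17
    alleles_per_locus: int = 8
    n_small_saplings: int = 150
    n_large_saplings: int = 150
    bin_edges: tuple = fsgs.DEFAULT_BIN_EDGES
    first_bin_upper: float = 30.0
    n_perm: int = 4999                     # FSGS permutations
    sigma: float = 250.0                   # intensity bandwidth, m
    n_sim: int = 999                       # PCF envelope simulations
    pcf_r_max: float = 100.0
    parentage_threshold: float = 0.5
    alpha: float = 0.05
    nm_starts: int = 4
    regimes: list = field(default_factory=lambda: [
        RegimeConfig("low_hunting", m_s=0.8, delta_s=1000.0),
        RegimeConfig("high_hunting", m_s=0.05, delta_s=30.0),
    ])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        regimes = [RegimeConfig(**r) for r in raw.pop("regimes", [])]
        cfg = cls(**raw)
        if regimes:
            cfg.regimes = regimes
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["bin_edges"] = list(d["bin_edges"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def simulate_regime(cfg: StudyConfig, regime: RegimeConfig, seed: int,
                    window: StudyWindow, afreq):
    """One regime's synthetic site: genotyped adults plus two sapling cohorts."""
    rng = np.random.default_rng(seed)
    adults = draw_founder_genotypes(
        simulate_adults(window, cfg.adult_intensity, seed=rng),
        afreq, seed=rng)
    params = regime.params()
    n_small = regime.n_small_saplings or cfg.n_small_saplings
    n_large = regime.n_large_saplings or cfg.n_large_saplings
    small, truth_s = simulate_offspring_cohort(
        adults, params, n_small, window, afreq, seed=rng,
        cohort="small_sapling", id_prefix="S")
    large, truth_l = simulate_offspring_cohort(
        adults, params, n_large, window, afreq, seed=rng,
        cohort="large_sapling", id_prefix="L")
    return adults, small, large, truth_s + truth_l


def run_study(cfg: StudyConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline on synthetic data; returns the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    window = StudyWindow.rectangle(cfg.window_size, cfg.window_size)
    afreq = simulate_allele_frequencies(cfg.n_loci, cfg.alleles_per_locus,
                                        seed=cfg.seed)
    io.write_window(window, out / "window.geojson")

    summary: dict = {"regimes": {}}
    slopes_by_regime = {}
    for k, regime in enumerate(cfg.regimes):
        log.info("simulating regime %s", regime.name)
        rdir = out / regime.name
        rdir.mkdir(exist_ok=True)
        adults, small, large, truth = simulate_regime(
            cfg, regime, cfg.seed + 1000 * (k + 1), window, afreq)
        pops = {"adult": adults, "small_sapling": small, "large_sapling": large}
        full = pd.concat([p.to_frame() for p in pops.values()])
        full.to_csv(rdir / "population.csv", index=False)
        truth_frame(truth).to_csv(rdir / "truth.csv", index=False)

        reg: dict = {}
        # demography
        dbh = full["dbh"].to_numpy()
        tab = demography.size_class_histogram(dbh, np.repeat(regime.name, len(full)))
        tab.frequencies.to_csv(rdir / "size_classes.csv")
        reg["cohort_totals"] = tab.cohort_totals[regime.name].to_dict()

        # point pattern: clustering of each cohort
        reg["g10"] = {}
        grid = np.linspace(5.0, cfg.pcf_r_max, 39)
        for name, pop in pops.items():
            res = pointpattern.pcf_inhom(pop.xy, window, r_grid=grid,
                                         sigma=cfg.sigma)
            reg["g10"][name] = res.g_at(10.0)

        # FSGS per sapling cohort
        reg["sp"] = {}
        for name in ("small_sapling", "large_sapling"):
            curve = fsgs.sp_statistic(pops[name], afreq,
                                      first_bin_upper=cfg.first_bin_upper,
                                      bin_edges=cfg.bin_edges)
            reg["sp"][name] = dict(sp=curve.sp, b_ld=curve.b_ld, f1=curve.f1,
                                   sp_se=curve.sp_se)
            if name == "small_sapling":
                slopes_by_regime[regime.name] = curve.per_locus_slopes

        # neighborhood model on small saplings
        log.info("fitting neighborhood model (%s)", regime.name)
        data = neighborhood.NeighborhoodData(small, adults, afreq)
        fit = neighborhood.fit_neighborhood_model(data, n_starts=cfg.nm_starts,
                                                  seed=cfg.seed + 7 * (k + 1))
        assigns = neighborhood.assign_parentage(fit, cfg.parentage_threshold)
        assigns.to_csv(rdir / "parentage.csv", index=False)
        imm = neighborhood.immigration_summary(assigns, alpha=cfg.alpha)
        imm.to_csv(rdir / "immigration.csv", index=False)
        reg["fit"] = dict(s_o=fit.params.s_o, m_p=fit.params.m_p,
                          m_s=fit.params.m_s, delta_s=fit.params.seed.delta,
                          b_s=fit.params.seed.b, delta_p=fit.params.pollen.delta,
                          b_p=fit.params.pollen.b, loglik=fit.loglik)
        reg["seed_immigration"] = float(
            imm.loc[imm["type"] == "seed", "proportion"].iloc[0])
        reg["dispersal_categories"] = (assigns["category"].value_counts(normalize=True)
                                       .to_dict())
        summary["regimes"][regime.name] = reg

    # cross-regime Sp comparison (paired t over per-locus slopes)
    names = list(slopes_by_regime)
    if len(names) == 2:
        t, dfree, p = fsgs.compare_sp_paired_t(slopes_by_regime[names[0]],
                                               slopes_by_regime[names[1]])
        summary["sp_comparison"] = dict(groups=names, t=t, df=dfree, p=p)

    # seed-fate experiment under the protective-substrate regime
    design = distance_density_design()
    records = simulate_seed_fate_experiment(
        design, {"intercept": 0.5, "distance": -0.01, "hunting[high]": -0.8,
                 "distance:hunting[high]": -0.02},
        unit_sd=0.5, seed=cfg.seed + 99)
    seed_fate_frame(records).to_csv(out / "seed_fate.csv", index=False)
    best, trace = seedfate.stepwise_selection(
        records, ["density", "distance", "hunting", "distance:hunting"],
        alpha=cfg.alpha, group="unit", forced=("hunting",))
    trace.to_csv(out / "seed_fate_selection.csv", index=False)
    summary["seed_fate_terms"] = best.terms

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    manifest = {
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "outputs": {p.name: _hash_file(p) for p in sorted(out.rglob("*"))
                    if p.is_file() and p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return summary
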