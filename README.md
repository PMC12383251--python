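# seeddisp

Spatial-genetic and dispersal inference for mapped tree populations whose
seeds are moved by large frugivores. The package was built around a
question from tropical forest ecology: when the main disperser of a
large-seeded tree (here, an African-ebony-like dioecious tree dispersed by
forest elephants) is lost, does the loss show up in the spatial and genetic
structure of the saplings — and can the change be measured from a mapped,
genotyped inventory plot?

It provides, as importable modules with a thin CLI on top:

- **`simulate`** — spatially explicit dioecious populations with
  microsatellite genotypes, offspring cohorts generated under an explicit
  seed/pollen dispersal model with known parentage, genotyping error, and
  factorial seed-fate experiments. Every analysis below can therefore be
  validated against ground truth.
- **`fsgs`** — fine-scale spatial genetic structure: pairwise Loiselle/Nason
  kinship `F_ij`, kinship–distance curves `F(r)` (bins 0/30/100/…/3200 m,
  jackknife-over-loci SEs), the regression slope `b_Ld` of `F_ij` on
  `ln r_ij`, and the statistic `Sp = −b_Ld / (1 − F₍₁₎)` with permutation
  envelopes (4999 permutations by default) and paired-t comparisons across
  per-locus slopes.
- **`pointpattern`** — the inhomogeneous pair-correlation function `g(r)`
  with a σ = 250 m Gaussian intensity surface, Ripley isotropic edge
  correction, Epanechnikov smoothing (Stoyan bandwidth), 999-simulation
  Monte Carlo envelopes, and split-half pooled curves.
- **`neighborhood`** — maximum-likelihood neighborhood model: each offspring
  is a mixture over seed immigration (`m_s`), selfing (`s_o`), background
  pollen (`m_p`) and candidate parent pairs weighted by exponential
  power–von Mises kernels (mean distances `δ_s`, `δ_p`; shapes `b_s`, `b_p`,
  with `b = 2` Gaussian and `b = 1` exponential), with per-locus
  mistyping-tolerant Mendelian transition probabilities. Parentage is
  assigned from the fitted posterior (threshold 0.5) and classified as
  undispersed (< 20 m), dispersed within plot, or immigrant.
- **`demography`** — dbh size classes (< 5 / 5–10 / ≥ 10 cm), two-sample
  Kolmogorov–Smirnov, Greenwood ECDF bands, Fisher's exact test with the
  conditional-ML odds ratio, and prevalence contrasts.
- **`seedfate`** — logistic models of binary seed/seedling fates with an
  optional unit-level random intercept (adaptive Gauss–Hermite quadrature),
  backward LRT model selection at α = 0.05, and Holm-adjusted pairwise
  odds-ratio contrasts.

## Worked example

The numbered scripts under `analysis/` run a two-regime synthetic study:
a *low-hunting* regime (long-distance seed dispersal, `δ_s` = 1000 m, seed
immigration `m_s` = 0.8) and a *high-hunting* regime (gravity-like
dispersal, `δ_s` = 30 m, `m_s` = 0.05), each a 2 km × 2 km plot with ~100
adults and 17 microsatellite loci:

```sh
python analysis/01_simulate.py      # populations + true parentage
python analysis/02_demography.py    # size classes, K-S, Fisher OR
python analysis/03_point_pattern.py # inhomogeneous PCF per cohort
python analysis/04_fsgs.py          # kinship curves and Sp
python analysis/05_dispersal.py     # neighborhood-model fits, parentage
python analysis/06_seed_fate.py     # seed-fate GLMMs and contrasts
```

The summary tables of this run are shipped under `results/` (the raw
per-seed and per-pair tables are regenerated by the scripts); the console
output reads:

```
low_hunting   small_sapling  g(10) =   1.18      Sp =  0.0005 (p = 0.57)
high_hunting  small_sapling  g(10) =  19.89      Sp =  0.0122 (p = 0.002)
regime contrast (small_sapling): t(16) = 5.55, Holm p = 4.4e-05
low_hunting : m_s fitted 0.82 (true 0.8)
high_hunting: m_s fitted 0.11 (true 0.05); mean seed dispersal 18 m (true 30)
```

Reading: under gravity-like dispersal the sapling cohort is ~20× more
clustered than random at 10 m, its spatial genetic structure is an order of
magnitude stronger (`Sp` 0.0122 vs 0.0005; the paired t over 17 per-locus
slopes gives t(16) = 5.55), and the fraction of saplings whose mother is not
found in the plot collapses from 82% to 11% — the same qualitative signature
the method chain is designed to detect in field data, here recovered from
known simulation truth.

The same operations are available as a CLI for external tables
(population CSV with `allele1/allele2` genotype columns, GeoJSON windows,
GenePop export):

```sh
seeddisp simulate population --seed 3 --out demo/
seeddisp fsgs demo/population.csv --n-perm 999 --out demo/fsgs
seeddisp nm-fit demo/offspring.csv demo/population.csv --out demo/nm
```

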