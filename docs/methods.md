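# Methods

This note documents the models implemented in `seeddisp`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter.

## Kinship and fine-scale spatial genetic structure

Pairwise kinship uses the Loiselle/Nason product-moment estimator. For a
locus with reference allele frequencies `p_a` and half-dosages
`x_ia ∈ {0, ½, 1}`:

    F_l(i,j) = [ Σ_a (x_ia − p_a)(x_ja − p_a) + Σ_a p_a(1−p_a)/(n_l−1) ]
               / Σ_a p_a(1−p_a)

with `n_l` the number of gene copies behind the frequency estimate. The
multilocus value is the ratio of summed numerators to summed denominators
over the loci typed in both individuals — equivalently a weighted mean of
per-locus estimates with weights `Σ_a p_a(1−p_a)`. The estimator is
unbiased around 0 for non-relatives and anchors at 1/4 (full sibs) and 1/8
(half sibs); the calibration suite verifies both to ±0.02 over 500 simulated
pairs at 17 loci × 8 alleles.

The strength of structure is summarised by `Sp = −b_Ld / (1 − F₍₁₎)`, where
`b_Ld` is the OLS slope of *all pairwise* `F_ij` on `ln r_ij` (pairs at
`r = 0` excluded from the regression only) and `F₍₁₎` the mean kinship in
the first distance class (0–30 m by default; configurable). Regressing
pairwise values rather than bin means follows the standard Sp methodology.
Distance bins default to 0/30/100/200/400/800/1600/3200 m. Uncertainty:
delete-one-locus jackknife for `F(r)`, `b_Ld` and `Sp`. Significance:
spatial positions are permuted against genotypes (default 4999
permutations); envelopes are the α/2 and 1−α/2 empirical quantiles, and
p-values use the add-one rank rule, so `p ≥ 1/(n_perm+1)`. Two groups typed
at the same loci are compared by a two-sided paired t over per-locus slopes
(17 loci → df 16), with Holm's step-down correction across a user-supplied
comparison family. Cohorts are analysed separately; reference allele
frequencies default to the pooled analysis set.

## Inhomogeneous pair correlation

The intensity surface is a Gaussian kernel estimate with σ = 250 m and
Diggle's edge correction (each kernel divided by its in-window mass), so the
intensity integrates to the point count; at data points the leave-one-out
value is used. The PCF estimator sums, over ordered pairs,

    k_h(r − d_ij) · e_ij / (2π d_ij · λ(x_i) λ(x_j) · |W|)

with Ripley isotropic weights `e_ij` (fraction of the circle through `x_j`
centred at `x_i` inside the window; computed analytically-fast for
rectangles, by 128-point arc discretization for windows with holes),
an Epanechnikov kernel with Stoyan's bandwidth `h = 0.15/√λ̄`, a
renormalization of the intensity with power two (the reciprocal-intensity
sum is scaled to the window area and enters squared), and a boundary
renormalization at `r < h` for the kernel mass lost below zero distance.
On complete spatial randomness the mean of `g` over 10–100 m is ≈ 0.97
(the small residual negative bias comes from estimating the intensity from
the same pattern; with a power-one renormalization the mean is ≈ 1.01, but
power two is kept as the study setting). Envelopes simulate an
inhomogeneous Poisson process from the estimated intensity, re-estimating
the intensity inside every simulation so that estimation noise is
propagated; with 999 simulations and α = 0.05 the pointwise envelope is the
25th smallest/largest simulated value. `g(10 m)` — roughly an adult crown
radius — is exposed as a named summary. Split-half pooled curves average
per-half PCFs with a t CI.

## Neighborhood dispersal model

Dispersal kernels are exponential power–von Mises location densities

    f(d, θ) ∝ exp(−(d/a)^b) · vM(θ; axis, κ),   a = δ·Γ(2/b)/Γ(3/b)

parameterised by the mean dispersal distance δ (so the reciprocals `d_s`,
`d_p` familiar from the field literature are `1/δ`); `b = 2` is Gaussian,
`b = 1` exponential, `b < 1` fat-tailed; κ = 0 (isotropy) is the default
because no anisotropy axis is reported for the system. Kernel sampling uses
`(d/a)^b ~ Gamma(2/b)`.

Each offspring's likelihood is the mixture

    L_o = m_s·P_bg(g_o) + (1−m_s)·Σ_j w_s(o,j)·[ s_o·T(g_o|g_j,g_j)
          + m_p·T(g_o|g_j,BG) + (1−s_o−m_p)·Σ_k w_p(j,k)·T(g_o|g_j,g_k) ]

where `w_s` are seed-kernel densities normalized over candidate mothers
(females plus unknown-sex adults), `w_p` pollen-kernel densities normalized
over candidate fathers (males plus unknown-sex; the same individual cannot
be its own mate outside the selfing term), `P_bg` the Hardy–Weinberg
genotype probability, and `T` the transition probability multiplied across
loci. Offspring with a field-identified mother contribute the reduced
paternity-only bracket. Mistyping: with probability `e_l` the observed
genotype at locus *l* is an independent HWE draw, making `T` mismatch
tolerant; parents' missing genotypes contribute HWE gametes. Candidates'
fecundities are uniform a priori.

Fitting maximizes the total log-likelihood by multi-start L-BFGS-B (default
8 starts, deterministic seed-derived perturbations) on transformed scales:
log for δ, b, κ; logit for `m_s`; a two-logit stick-breaking for the
`(s_o, m_p)` simplex. Genotype transition tensors are precomputed once per
mistyping configuration, so a likelihood evaluation is a few einsums;
bounds (b ∈ [0.2, 5], δ ∈ [1, 10⁵] m) are reported as boundary flags when
active. Per-locus `e_l` is estimated by cyclic per-locus profile likelihood
at fixed dispersal parameters; the borrowed-rate workflow (estimate on a
reference dataset, fix elsewhere) is the intended use.

Parentage: posterior over (mother, father) configurations from the fitted
mixture; a mother is assigned when her marginal posterior reaches 0.5, and
offspring are classified as not dispersed (< 20 m), dispersed within plot,
or dispersed from outside (no assignable mother). Immigration proportions
carry Wilson 95% intervals.

**Identifiability caveat.** When `m_s` is large and δ_s approaches the plot
size, the seed-kernel scale is weakly identified: locally born offspring are
nearly uniformly placed, so the normalized mother weights carry little
information about δ_s (the fitted value can drift far above the truth while
`m_s`, `s_o`, `m_p` and the pollen kernel remain well estimated). Parameter
recovery is validated at δ_s = 500 m, m_s = 0.3 (10 replicates; every
parameter's mean within 2 replicate SDs of truth) and shape recovery at
m_s = 0: a fit to 300 offspring recovers `b_s` with sampling sd ≈ 0.2, so
replicate fits (the calibration suite uses the median of 15) are
recommended when the shape itself is the quantity of interest.

## Demography and exact statistics

Size classes use 2-cm dbh bins standardized per site, with cohort
thresholds at 5 and 10 cm. The two-sample K-S test uses the exact
enumeration p-value when the smaller sample has ≤ 10 observations and the
asymptotic distribution otherwise. ECDF bands use Greenwood's variance in
its no-censoring form `F(1−F)/n`, clipped to [0, 1] and monotonized.
Fisher's exact test reports the *conditional maximum-likelihood* odds ratio
under the noncentral hypergeometric likelihood — the convention under which
a zero cell gives OR = 0 — with a CI from inverting the exact one-sided
tail tests, all computed from vectorized log-binomial weights (agreement
with R's fisher.test: OR to 1e-5). The prevalence contrast `1 − p₂/p₁`
uses a log-ratio normal CI.

## Seed-fate models

Multi-category fates are collapsed to the binary outcomes actually
analysed (e.g. removed/germinated or not). Fixed effects are fitted by
damped Newton/IRLS to gradient norm < 1e−8, with explicit detection of
complete separation and aliasing. A single random intercept (experimental
unit) is integrated by adaptive Gauss–Hermite quadrature (inner Newton for
the conditional mode, default 15 nodes; one node reproduces the Laplace
approximation), cross-checked against lme4::glmer. A single grouping level
replaces a nested watershed structure deliberately: the nested level was
shown to change nothing in the motivating analysis, and one level keeps the
integral one-dimensional. Model selection is backward elimination by LRT at
α = 0.05 (interactions removed before their main effects; terms central to
the design can be forced to stay), and treatment effects are Holm-adjusted
Wald contrasts on the logit scale — Holm rather than a multivariate-t
(Tukey) adjustment, trading a little power for exactness-free simplicity.
Seed density (2 vs 25) is coded categorical.

## Synthetic-data generator

The generator is first-class, tested code, and defines the conditions under
which everything above is validated: 2 km × 2 km windows (optionally with
exclusion holes), adult intensity 2.5×10⁻⁵ m⁻² (~100 adults), dioecy with
Bernoulli(½) sexes, log-normal adult dbh (median 25 cm, log-sd 0.5,
truncated at the 10-cm adult threshold), 17 loci × 8 alleles from a
symmetric Dirichlet(1), Hardy–Weinberg founder genotypes, Mendelian
offspring with the mixture structure of the neighborhood model
(out-of-window displacements redrawn, i.e. truncation rather than
wrapping), per-allele-copy mistyping, and factorial seed-fate designs
(2/20/50 m × densities 2/25 on opposite transects; substrate treatments
fruit/naked/dung(+gut) replicated in 5-seed groups) with logit-linear
outcomes and Normal unit intercepts. Immigrant genotypes come from the same
allele-frequency pool — no background differentiation — which is the
simplest null consistent with treating immigration as an unstructured
background; a differentiated pool is the obvious extension.

The two study regimes used in `analysis/` are: long-distance dispersal
`δ_s = 1000 m`, `m_s = 0.8` (seed immigration dominating, as under intact
megafauna) versus gravity-like `δ_s = 30 m`, `m_s = 0.05`; both with
pollen `δ_p = 300 m`, `s_o = 0.05`, `m_p = 0.2`. These values were set
from the magnitudes the motivating system reports (immigrant fractions of
~84% vs ~16%, pollen distances of 250–450 m, sapling clusters below 50 m)
and are not tuned further.

What the generator does *not* emulate — and what passing tests therefore do
not establish about field data: multi-generation pedigrees (saplings are one
generation from the adults, so cohort kinship structure is sib-family based
rather than an equilibrium isolation-by-distance pattern), fecundity
differences among adults, spatially structured immigrant sources,
habitat-driven intensity gradients (windows are homogeneous unless holes
are supplied), allele-frequency drift between cohorts, and genotyping
artefacts beyond random mistyping (no allelic dropout or stutter).

## Numerical choices

- All randomness flows through `numpy.random.Generator` seeds; same seed →
  byte-identical outputs (tested), and the pipeline manifest records output
  hashes.
- Kernel weights are exp-normalized from log densities, so extreme δ, b
  values underflow gracefully during optimization.
- Genotype products across 17 loci are accumulated in linear space; the
  smallest relevant magnitudes (~10⁻²⁵) are far from double underflow.
- Empty distance bins are reported as missing, never as zero kinship; an
  empty first distance class raises an error suggesting a wider class.
- Permutation and envelope ranks follow the add-one convention; envelope
  levels are exact pointwise, not simultaneous.
- The acceptance script scales its experiments to single-CPU minutes:
  50 CSR patterns of ~500 points and 15 replicate kernel fits of 300
  offspring each; the type-I calibration runs use 1000 replicates with 199
  permutations each.
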