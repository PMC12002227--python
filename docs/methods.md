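# Methods

## Statistical model

### De novo burden

The per-gene, per-class mutability μ<sub>gc</sub> is the probability of one
de novo variant of class *c* (synonymous, T-mis, D-mis, LOF) arising in gene
*g* per live birth. The expected DNM count in *n* trios is *n·μ<sub>gc</sub>*
with no additional ploidy factor — the mutability is defined per birth, not
per haploid genome. The burden test is the exact upper Poisson tail
*P(X ≥ O)* including the observed count (conservative for enrichment);
gene-set burden sums O and E over the set before testing, so expectations
are additive by construction. The DNM attributable fraction is
max(0, O − E)/n per proband, floored at zero.

### Very rare variant filter and case–control burden

A variant is "very rare" when its allele frequency is ≤ 10⁻⁵ in both the
BRAVO and ESP population databases (missing = absent = 0) and its
within-cohort frequency AC/AN is ≤ 1.3×10⁻⁴. The cohort filter is read as
*retaining* variants at or below the threshold: its purpose is to restrict
to very rare alleles, so the removal direction can only be "above".

Case and control capture territories are harmonized to their intersection
(BED-convention 0-based half-open intervals; variant positions are 1-based
VCF-convention, converted in one place), and chromosome denominators are
scaled by the per-gene callable fraction, rounded half-up with a floor of
one chromosome. The burden test is the one-tailed Fisher exact test
(hypergeometric upper tail) in the case-enrichment direction only;
depletion is never significant. The case–control attributable fraction is
max(0, f_case − f_control)·2 per diploid proband.

### Transmission disequilibrium

Each parental heterozygous allele contributes one informative transmission.
χ² = (T − U)²/(T + U) with 1 df and **no continuity correction** — this
choice exactly reproduces the three published worked statistics
(118/34 → 9.5×10⁻¹²; 68/29 → 7.5×10⁻⁵; 16/3 → 2.8×10⁻³). The genotypic
risk ratio is T/U (multiplicative model), +∞ when U = 0. The TDT
attributable fraction is max(0, T − (T+U)/2)/n trios.

### Meta-analysis and joint-local FDR

Per gene the two one-sided p-values combine via Fisher's method
(χ²₄ tail of −2·Σ log p; p-values are floored at 10⁻³⁰⁰ first). For the
empirical-Bayes step each test statistic is mapped to a z-score.
Because both tests are discrete with tiny expected counts (most genes have
zero DNMs), the plain tail has a point mass at p = 1 and even the mid-p
variant leaves lattice clusters that a Gaussian null cannot represent. The
z-transform therefore uses the **randomized probability-integral
transform** P(X > x) + V·P(X = x) with V ~ Uniform(0,1) (the construction
behind randomized quantile residuals), which is exactly uniform under the
null. The randomization stream is seeded from the run configuration, so
results are reproducible; reported p-values remain the deterministic
conservative tails. z-scores are clipped to ±8.

The z-pairs follow a two-component mixture: a **fixed** standard bivariate
normal null (both inputs are one-sided p-values, uniform under the null,
hence independent standard normal after transform) with weight π₀, and a
free alternative with componentwise non-negative mean and full covariance,
fitted by EM. Three safeguards address the known failure modes of plug-in
local-FDR fits:

- a weak Beta prior on π₀ (pseudo-count strength 0.1·n) resolves the flat
  likelihood when the components coincide (pure-null samples);
- a generalized-EM step guard rejects any M-step that would lower the
  penalized log-likelihood (possible when the mean clips at zero), so the
  trace is always non-decreasing;
- a BIC comparison against the null-only model — the same G=1 vs G=2
  selection mixture packages perform — collapses the fit to π₀ = 1 when
  the alternative component is not supported. Without this gate the free
  alternative fits the extreme corner of a pure-null sample and
  manufactures false discoveries.

local fdr(g) = π₀φ₀(z_g) / [π₀φ₀(z_g) + (1−π₀)φ₁(z_g)]; genes are ranked
by local fdr and the JL-FDR at rank k is the mean local fdr of the top-k
set, which is non-decreasing by construction; significance is JL-FDR ≤
0.05. Benjamini–Hochberg q-values (via statsmodels) are provided for the
single streams, a Bonferroni threshold of 0.05/248 for single-gene lookups,
and the exome-wide constant 2.6×10⁻⁶ is a configuration value, not derived.
round((1−π₀)·n) predicts how many panel genes will ultimately prove
significant.

### Inflation diagnostics

λ is the median of the χ²₁ statistics implied by the p-values divided by
the null median 0.4549; λ₁₀₀₀ = 1 + (λ−1)·1000/n rescales to a 1,000-sample
cohort (single-statistic-per-gene form). Synonymous and T-mis streams act
as negative controls and should sit near 1.

### Risk-gene-count MLE

For each candidate risk-gene count R on a grid, cohorts are simulated:
R genes drawn proportionally to damaging mutability (uniform sampling
available by flag), damaging DNM means multiplied by an enrichment factor
(profiled over a small grid), counts drawn Poisson. The summary statistic
is the pair (genes with ≥1 hit, genes with ≥2 hits); the empirical
likelihood of the observed pair uses the simulated joint frequency table
with add-one smoothing (one extra slot for unseen outcomes). The MLE is the
grid argmax; the 95% CI collects grid points within 1.92 log-likelihood
units. With 200 simulations per grid point the CI is honest but wide; in
recovery experiments (20 planted risk genes, 10× enrichment) it covered
the truth in 20/20 repetitions.

### Subgroup association and clinical comparisons

The gene × phenotype grid (cardiac subtypes plus EC/NDD categories) is
meta-analyzed per cell with the subgroup's trio count and chromosome
denominator, and JL-FDR is applied jointly across the whole grid. Clinical
2×2 tables use the two-sided Fisher exact test with the point-probability
rule (sum over tables no more probable than observed), which reproduces
the published feeding-difficulty example (2/7 vs 15/18 → p = 1.7×10⁻²).
Continuous features use the Wilcoxon rank-sum test, exact when both groups
have ≤ 10 untied values, normal approximation with tie correction
otherwise. The non-randomness Monte-Carlo test permutes phenotype labels
and uses the Pearson χ² of the gene-category × phenotype-category table
with p = (1 + #{perm ≥ obs})/(1 + n_perm). Protein-region enrichment uses
1-based inclusive residue coordinates and the cysteine predicate
(aa_ref = C) xor (aa_alt = C), so C→C and non-C→non-C are both negative.

## Synthetic cohorts

The generator emulates the statistical structure of a targeted-panel study:

- **Mutability.** Per-gene total mutability is log-normal (σ = 0.7) with
  mean 10⁻⁴ per birth — representative of the large, mutation-prone loci
  chosen for disease panels — split across classes by a Dirichlet around
  (0.30, 0.40, 0.20, 0.10) for (synonymous, T-mis, D-mis, LOF).
- **Scale defaults.** 3,887 trios, 7,668 singletons, 133,743 diploid
  controls, 248 genes. Damaging-class DNM enrichment defaults to 10×
  (between the reported panel-wide LOF 14.3× and D-mis 6.1×), transmission
  probability to 0.78 (the observed LOF transmitted fraction), and the
  per-gene parental damaging-carrier probability to 5×10⁻⁴
  (back-calculated from ~250 parental damaging alleles across 60 genes in
  3,887 trios). Per-gene callable fractions are uniform on (0.9, 1.0).
- **Mechanism.** DNM counts are Poisson(n·μ·e); parental heterozygotes are
  Binomial(2n, h) with class-level h proportional to mutability and
  transmitted with probability τ (0.5 off risk genes); singleton probands
  carry alleles with probability 2hτ; controls are Binomial draws at the
  population frequency h/2 over coverage-masked chromosomes. Every site is
  unique (so rarity filters pass by construction) unless site reuse is
  enabled. Proband phenotypes follow a categorical model: each risk gene is
  linked to a cardiac subtype, carriers receive it with concordance 0.8,
  and NDD/EC flags are elevated for carriers of NDD-associated risk genes.
- **One stream.** All draws derive from a single NumPy generator keyed by
  the config seed; identical config + seed gives byte-identical outputs.

What the generator does **not** model: read-level sequencing error,
population structure and relatedness, recurrent mutation hotspots beyond
the optional site-reuse knob, per-base (as opposed to per-gene) coverage
variation, winner's-curse ascertainment of the panel, and linkage between
sites. Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the stated generative model, not that real
cohorts satisfy that model.

## Numerical choices and degenerate inputs

- p-value floor 10⁻³⁰⁰ before log/inverse-normal transforms; z cap ±8.
- EM: initialization π₀ = 0.9, alternative mean = mean of pairs with both
  z > 1 (fallback (2,2)), covariance = identity + 10⁻⁶ ridge; tolerance
  10⁻⁶ log-likelihood units, cap 1000 iterations.
- Coverage adjustment rounds half-up, minimum 1 chromosome.
- Enrichment sentinels: +∞ when only cases carry alleles, NaN when neither
  arm does. GRR +∞ when U = 0.
- Duos (one listed parent) are treated as singletons with a warning; a
  listed parent without its own pedigree row is a structural error.
- Multi-allelic variant rows are rejected; inputs must be pre-split.
- Genes absent from the panel are skipped with a reject record, not an
  error; empty gene sets and all-zero 2×2 tables are errors.

## Problem sizes used in the test suite

Unit and property tests run on 20–60-gene cohorts with 300–2,000 trios,
sized so that planted signals are detectable while the full suite stays
fast; the calibration and recovery checks run at the study's scale
(248 genes, 3,887 trios, 25,000 control chromosomes; 200 null replicates,
20 recovery repetitions). The acceptance script pools three full-scale
cohorts for its recovery estimates because a single cohort yields only
~60–100 informative transmissions at realistic carrier frequencies.

## Known limitations

- The JL-FDR construction (running mean of local fdrs) is one pinned
  reading of joint-local FDR; other two-dimensional rejection-region shapes
  exist. The BIC gate makes the procedure conservative near the global
  null.
- The risk-gene-count likelihood is an empirical Monte-Carlo approximation
  over a two-dimensional summary; its CI width reflects that coarseness.
- Randomized z-transforms make the mixture stage's exact output depend on
  the configured seed (reported p-values do not).
- The coverage model is per-gene; per-base coverage adjustment is out of
  scope.
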