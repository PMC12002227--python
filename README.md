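# chdburden

Rare-variant gene burden analysis for congenital heart disease (CHD) cohorts
of parent–offspring trios and singleton probands, with a synthetic-cohort
generator that provides ground truth for every analysis stage.

## The problem

Dominant CHD genes reveal themselves through two independent signals in a
sequenced proband cohort:

1. **De novo mutation (DNM) burden.** Under the null, the number of de novo
   variants of functional class *c* in gene *g* across *n* trios is
   Poisson with mean *n·μ<sub>gc</sub>*, where *μ<sub>gc</sub>* is the
   per-live-birth mutability of that gene/class. Enrichment is *O/E* and the
   test is the upper Poisson tail *P(X ≥ O)*.
2. **Case–control burden of very rare transmitted/unphased variants (TUVs).**
   Alleles with population MAF ≤ 10⁻⁵ (BRAVO and ESP) and within-cohort
   MAF ≤ 1.3×10⁻⁴ are compared against reference-population allele counts by
   one-tailed Fisher's exact test, after per-gene harmonization of capture
   territory and coverage-scaled chromosome denominators.

Per gene, the two one-sided p-values are combined by Fisher's method and
mapped to a bivariate evidence vector *z = (z<sub>DNM</sub>, z<sub>CC</sub>)*.
Across genes, *z* is modeled as a two-component mixture — a fixed standard
bivariate normal null with weight π₀ and a free alternative component fitted
by EM — giving each gene a joint-local false discovery rate (JL-FDR):
local fdr = π₀φ₀(z) / [π₀φ₀(z) + (1−π₀)φ₁(z)], with the rejection-set FDR
taken as the running mean of local fdrs in rank order. (1−π₀)·n estimates
how many panel genes will ultimately prove significant.

Independent confirmation comes from the **transmission disequilibrium test
(TDT)**: a parental heterozygous very rare allele is transmitted to an
affected child with probability ½ under the null, so with T transmitted and
U untransmitted alleles, χ² = (T−U)²/(T+U) on 1 df, and the genotypic risk
ratio is estimated by T/U. Attributable fractions (the share of probands
explained) are the excess of observed over expected carriers, per proband.

The package also covers phenotype-subgroup association (cardiac subtype,
extracardiac and neurodevelopmental flags) with JL-FDR over the gene ×
phenotype grid, clinical 2×2 (two-sided Fisher) and Wilcoxon rank-sum
comparisons, Monte-Carlo contingency permutation tests, protein-region
variant-class enrichment (e.g. cysteine-altering missense in EGF domains),
QQ/λ₁₀₀₀ inflation diagnostics, and a Monte-Carlo maximum-likelihood
estimate of the number of risk genes on a panel.

## Worked example

```python
from chdburden import tdt_test
r = tdt_test(118, 34)   # panel-wide LOF transmissions in 3,887 trios
print(f"transmitted={100*r.transmitted_fraction:.0f}% "
      f"chi2={r.chi2:.2f} p={r.p:.1e} GRR={r.grr:.1f}")
```
```
transmitted=78% chi2=46.42 p=9.5e-12 GRR=3.5
```
118 of 152 parental loss-of-function alleles reached the affected child —
a 78% transmission rate whose chi-square p-value of 9.5×10⁻¹² rules out
Mendelian chance; carriers are ~3.5× as likely to be affected.

End to end on a synthetic cohort with known truth (248 genes, 3,887 trios,
7,668 singletons, 20 risk genes with 10× damaging-DNM enrichment and 0.75
transmission):

```python
from chdburden import (CohortConfig, sample_mutabilities, simulate_cohort,
                       analyze_cohort)
mut = sample_mutabilities(248, seed=1)
cfg = CohortConfig(risk_gene_fraction=20/248, dnm_enrichment=10.0,
                   transmission_prob=0.75, seed=4)
cohort = simulate_cohort(cfg, mut)
res = analyze_cohort(cohort.variants, mut, cohort.controls, cohort.coverage,
                     n_trios=cfg.n_trios, n_singletons=cfg.n_singletons, seed=4)
print(res.summary["significant_genes"], round(res.summary["pi0"], 3))
```
```
['G0167', 'G0215'] 0.945
```
Both discoveries are planted risk genes; the mixture estimates that 94.5% of
panel genes carry no signal at this cohort size (the planted truth is
228/248 = 91.9%), and the synonymous-variant inflation factor λ₁₀₀₀ ≈ 0.92
shows the negative-control stream is clean.

A command-line interface mirrors the library:

```bash
chdburden simulate --outdir cohort/ --seed 1
chdburden run --config run.yaml
chdburden report --outdir results/
```

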