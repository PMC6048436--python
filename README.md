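# poolgea

Genome–environment association (GEA) analysis for pooled population
sequencing (Pool-Seq) data, with the full simulation machinery needed to
validate every stage on synthetic data.

Pool-Seq designs sequence one pooled DNA sample per population, so allele
frequencies are estimated from read counts rather than genotypes, and any
scan for environmental association must untangle three layers of noise —
read sampling, pool sampling, and shared demographic history. `poolgea`
is written for population geneticists running micro-geographic GEA
studies: tens to hundreds of plant or animal populations, each pooled,
scanned against climate covariates.

## What it implements

The core is a Bayesian hierarchical model. For SNP *i* in population *j*
(haploid pool size *n_j*, coverage *c_ij*):

```
pi_i     ~ Beta(a, b)                            across-population frequency
alpha_i  ~ N(pi_i 1 + delta_i beta_i z,          population frequencies
             pi_i (1 - pi_i) Omega)
x_ij     ~ Binomial(n_j, clip(alpha_ij, 0, 1))   pool allele count
y_ij     ~ Binomial(c_ij, x_ij / n_j)            reference read count
```

* **Ω (Omega)** — the scaled covariance of population allele
  frequencies, estimated under the core model (no covariate) by a
  Metropolis-within-Gibbs sampler with a conjugate inverse-Wishart step;
  the structure correction that makes everything downstream robust to
  drift and gene flow. Interleaved SNP subsampling, the Förstner–Moonen
  distance between estimates, and the SVD of Ω (genomic principal axes)
  are included.
* **XtX** — the variance of the Ω-standardized population frequencies;
  a differentiation statistic with neutral expectation J, used to scan
  for selection.
* **AUX model** — spike-and-slab regression of frequencies on a
  standardized covariate: a binary indicator δ_i per SNP switches the
  regression coefficient β_i on/off, the shared inclusion probability is
  learned (built-in multiple-testing adjustment), and evidence is
  reported as Bayes factors in deciban (10·log₁₀ BF).
* **Filtering** — the five-step post-calling cascade (unmapped
  populations, high/low relative coverage, quasi-constant frequency,
  near-monomorphic SNPs) with a per-step audit report.
* **Enrichment** — fold enrichment of annotation categories and of the
  XtX upper tail within the top-BF tail, with circular-permutation nulls
  (rotation along the genome preserves linkage structure) and BH-FDR.
* **Regions** — candidate regions from runs of ≥3 top SNPs separated by
  <10 kb, merged across covariates, with gene-model overlap from GFF3.
* **Spatial/climate** — Spearman pruning of covariates, climate PCA and
  range fractions, PCNM spatial eigenvectors (matches R vegan) with
  per-grain regressions, and the geography regression of genomic PCs.
* **Power study** — the full simulate → scan → ROC/PR loop across a grid
  of covariate–structure correlations.

## A worked example

```python
import numpy as np
from poolgea import (MCMCSettings, SimConfig, run_aux_scan,
                     simulate_dataset, simulate_pc_correlated_covariate)

config = SimConfig(n_pops=32, n_snps=4000, n_assoc=40, beta_effect=0.15,
                   omega_spec=("spiked", 0.9), seed=5)
omega = config.omega()
covariate, _ = simulate_pc_correlated_covariate(omega, 0.0, seed=6)
matrix, pops, truth = simulate_dataset(config, covariate=covariate)
scan = run_aux_scan(matrix, pops, omega, covariate,
                    MCMCSettings.quick(), seed=7)

assoc = truth.truth_mask(scan.snp_ids)
print(f"median BF of planted SNPs : {np.median(scan.bf_db[assoc]):.1f} dB")
print(f"neutral 99th percentile   : {np.quantile(scan.bf_db[~assoc], 0.99):.1f} dB")
```

prints (≈2 min on one CPU):

```
median BF of planted SNPs : 28.6 dB
neutral 99th percentile   : 7.3 dB
```

The 40 planted SNPs (frequency shift 0.15 per standard deviation of the
covariate) stand far above the neutral background: 28.6 dB is posterior
odds of several hundred to one for association, while 99% of the 3,960
neutral SNPs stay under 7.3 dB and only two exceed the conventional
20 dB "decisive" line. The scripts in `examples/` walk through each capability
the same way — simulation, filtering, Ω/XtX, scanning, enrichment,
regions, spatial grains, and the power study.

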