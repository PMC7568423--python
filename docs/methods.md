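# Methods

This note documents the statistical models, the synthetic data generator,
default parameters, and the numerical choices behind `genoprio`.

## 1. Bayesian GWAS–eQTL integration (`genoprio.bayes`)

**eSNPs.** For one eQTL dataset, the eSNPs of a gene are the (SNP, gene)
pairs with eQTL p ≤ `esnp_p` (default 1e-4, boundary inclusive). Duplicate
pairs collapse to the smallest p.

**LD pruning.** Per gene, eSNPs are scanned in ascending eQTL-p order and
kept only if their reference-panel r² with every already-kept eSNP is
≤ `r2_max` (default 0.8). This prevents one LD-duplicated signal from being
counted twice in the gene score. eSNPs absent from the panel are kept with a
warning (their LD is unknown).

**Per-SNP score.** Each retained eSNP contributes the approximate log Bayes
factor of its GWAS z-score (|z| from the two-sided p),

    ln BF(z; W) = ½ ln(1/(1+W)) + (z²/2) · W/(1+W),

which is the log ratio of the marginal likelihoods N(z; 0, 1+W) / N(z; 0, 1)
under a normal prior with variance `W` (default `prior_w = 0.1`) on the
standardized effect. It is negative at z = 0 and strictly increasing in z²,
so a GWAS-supported eSNP raises the gene score while a GWAS-null eSNP lowers
it; SNPs that are not eSNPs are ignored.

**Gene score and simulated p.** The gene LBF is the sum over its pruned
eSNPs. Its null distribution is estimated by Monte Carlo: each of `B`
replicates reassigns the genome-wide GWAS z-scores to SNPs by a uniform
random permutation, keeping the eSNP structure fixed, and recomputes every
gene's LBF. The simulated p is `(1 + #{null ≥ observed}) / (B + 1)` (never
zero; resolution 1/(B+1)). Benjamini–Hochberg q-values are attached across
genes. `B ≥ 100` is enforced; the default is 1000 (200 in the bundled
pipeline for speed).

The permutation null assumes the z pool is exchangeable across SNPs. Under
strong within-gene LD the observed LBF of a null gene is over-dispersed
relative to this null, so simulated p-values are exactly calibrated only for
LD-free SNP pools; with LD they are used as a ranking and screening
statistic, as the consensus design intends (see §7).

## 2. Gene-based GWAS test (`genoprio.gene_based`)

SNPs are assigned to a gene if they lie within `window_bp` (default 20 kb,
boundaries inclusive) of the gene span on the same chromosome. With
z = beta/se per SNP, the gene statistic is `T = Σ z²`. Under the null, z is
multivariate normal with correlation R (panel-estimated), so

    E[T] = m,   Var[T] = 2 (m + Σ_{i≠j} r²_ij),

and T is approximated by the moment-matched scaled chi-square `c·χ²_f` with
`c = Var/(2E)`, `f = 2E²/Var` (Satterthwaite). Limits: a single SNP gives
back exactly its two-sided p; a perfectly LD-duplicated SNP (r = 1) leaves
the gene p unchanged.

**Panel-noise debias.** The panel estimate r̂² of a true correlation ρ has
expectation ≈ ρ² + (1−ρ²)²/n for panel size n; summing m(m−1) off-diagonal
terms inflates Var[T] and makes the gene p conservative when SNPs are nearly
independent. Each off-diagonal r̂² therefore enters the variance sum as
`max(0, r̂² − (1−r̂²)²/n)`. The clipping at zero retains roughly half of the
noise bias for truly null pairs (E[(1−χ²₁)₊] ≈ 0.48), a deliberately
conservative remainder.

The diagonal contribution to Var[T] uses the exact value m (the correlation
diagonal is 1 by construction); the ridge term (1e-6) is used only to
regularize the positive-semidefiniteness check, never the moments, so the
single-SNP limit holds to 1e-9.

Gene p-values are Bonferroni-corrected over the genes actually tested.

## 3. Resampling (`genoprio.resampling`)

**Overlap permutation test.** For gene lists A and B in background G, each
replicate draws |A| genes uniformly without replacement from G and counts
the overlap with B. With the add-one correction (default) the empirical p is
`(1 + #{overlap ≥ observed}) / (B + 1)`. Because the draw is uniform, the
overlap is exactly Hypergeometric(|G|, |B|, |A|); the exact tail serves as
an independent oracle in the tests and acceptance run (using the unbiased
raw-proportion estimator for that comparison).

**Null GWAS.** A binary phenotype with a fixed case count is assigned by a
seeded permutation of the panel samples; each SNP is tested with the
additive-dosage score test `χ² = n·r²` (r = trait–dosage correlation, 1 df),
asymptotically equivalent to per-SNP logistic regression under the null.
Monomorphic SNPs are flagged and carry p = 1. The genomic inflation factor
is `λGC = median(χ²)/0.455`.

## 4. Enrichment and expression validation

**Enrichment** (`genoprio.enrichment`): exact hypergeometric upper-tail
`P(X ≥ k)` per GMT term, term sizes intersected with the background first,
Holm step-down family-wise correction (plain Bonferroni also reported).

**Differential expression** (`genoprio.expression`): one-way fixed-effects
ANOVA across sample groups with Tukey HSD post-hoc pairwise p-values
(Tukey–Kramer for unequal group sizes); for two groups the ANOVA p equals
the pooled t-test p (F = t²). Per-group Pearson co-expression matrices
expose condition-specific co-regulation. Genes with zero within-group
variance everywhere are flagged degenerate rather than tested.

## 5. Consensus (`genoprio.consensus`)

A gene enters the consensus table only if its p-value is below `alpha`
(default 0.05, uncorrected — corrected q-values are carried in the report
but not filtered on) in every real analysis. The negative-control p and the
catalog flag are attached for reporting only. Venn region counts over up to
four analyses use membership-pattern keys ("1011" = in analyses 1, 3, 4).

## 6. Synthetic study generator (`genoprio.synthetic`)

The generator emulates a GWAS/eQTL colocalization study and returns the
ground truth needed for recovery and calibration analyses.

* **LD model.** Independent blocks of `block_size` SNPs (default 10); within
  a block, latent haplotype Gaussians follow an AR(1) with parameter
  `ld_decay` (default 0.9). Allele frequencies are Uniform(`maf_range`),
  default (0.05, 0.5).
* **Genotypes.** Hardy–Weinberg: a dosage is the sum of two independent
  haplotypes, each the indicator of its latent Gaussian falling below the
  frequency quantile. The *population* dosage correlation of this model is
  available in closed form via bivariate-normal orthant probabilities
  (`true_block_ld`, computed by Gauss–Legendre quadrature of the Plackett
  identity, accurate to ~1e-12 and verified against an independent numerical
  CDF).
* **GWAS.** Summary statistics on the z scale (se = 1): per block,
  z ~ MVN(R·λ₀, R) with R the exact population LD and λ₀ equal to the
  noncentrality (default 6) at each planted gene's causal SNP (the middle
  SNP of the gene's block). The reference panel is an independent
  finite-sample observation of the same population LD, as in a real study —
  this is what makes the gene-based test's panel-noise debias the correct
  correction within the simulated world.
* **eQTL datasets.** Each label has its own sample size (defaults 1490, 400,
  87); the skeleton of (SNP, gene) pairs is shared across labels while noise
  is independent per label. Planted genes' cis SNP z-scores are centred at
  the eQTL noncentrality (default 6) in *every* dataset — the standardized
  effect is noncentrality/√n per dataset — so each validation dataset
  carries equal evidence regardless of its size.
* **Expression.** Group sizes default to 44/72/38; planted
  differentially-expressed genes get a mean shift (default 3 sd) in the
  designated groups.
* **Determinism.** Every stage draws from
  `default_rng(SeedSequence([seed, crc32(stage_tag)]))`, so stages are
  independent, individually re-runnable, and bit-reproducible.

What the generator does *not* emulate: long-range LD, minor-allele-count
artefacts, population stratification, winner's-curse effect-size inflation,
probe-level expression noise, or case/control individual-level data.

## 7. Calibration designs

Each stochastic stage is calibrated on the global-null design its null
model assumes:

* the permutation simulated p requires an exchangeable z pool →
  `ld_decay = 0`, GWAS noncentrality 0, eSNP structure planted for all genes
  so every gene is scored;
* the Kolmogorov–Smirnov uniformity check requires (near-)independent gene
  p-values → a sparse SNP map (`spacing_bp = 10000`) so that ±20 kb windows
  barely overlap, in addition to `ld_decay = 0`;
* the null-GWAS score statistic is discrete at small sample sizes (an atom
  near p = 1 that fails KS even under a correct null) → calibration uses a
  large panel (3960 samples, 1980 cases).

Under heavy LD and a dense map these uniformity conditions do not hold by
construction (neighbouring windows share SNPs; the z pool is not
exchangeable), so calibration claims are made for the designs above, and
LD-rich designs are validated through planted-signal recovery instead.

## 8. Default parameters

| parameter | default | where |
|---|---|---|
| eSNP eQTL p threshold | 1e-4 | `bayes.identify_esnps` |
| Bayes factor prior variance W | 0.1 | `bayes.snp_log_bayes_factor` |
| LD-pruning r² ceiling | 0.8 | `bayes.prune_esnps_by_ld` |
| Monte-Carlo replicates B | 1000 (pipeline: 200) | `bayes.simulated_gene_pvalues` |
| gene window | ±20 kb | `gene_based.assign_snps_to_genes` |
| PSD-check ridge | 1e-6 | `gene_based.gene_statistic_p` |
| consensus alpha | 0.05 per analysis | `consensus.build_consensus_table` |
| genes / SNPs / panel | 1000 / 10000 / 500 | `synthetic.SyntheticTruth` |
| LD block size / decay | 10 / 0.9 | `synthetic.SyntheticTruth` |
| GWAS / eQTL noncentrality | 6 / 6 | `synthetic.SyntheticTruth` |
| eQTL dataset sizes | 1490, 400, 87 | `synthetic.DEFAULT_EQTL_DATASETS` |
| expression groups | 44 / 72 / 38 | `synthetic.DEFAULT_EXPRESSION_GROUPS` |
| SNP spacing | 1 kb | `synthetic.SyntheticTruth` |

## 9. Numerical notes

* p-values are clamped at 1e-300 before writing/using logs; parsed GWAS rows
  with p outside (0, 1] are rejected (strict) or dropped with line-numbered
  warnings.
* BED coordinates are converted between 0-based half-open (on disk) and
  1-based inclusive (in memory) at the I/O boundary only.
* BH and Holm adjustments delegate to `statsmodels.stats.multitest`; exact
  hypergeometric and chi-square tails to `scipy.stats`. Tests validate both
  against hand examples and enumeration oracles.
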