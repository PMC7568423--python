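"""Seeded generator for every input the prioritization pipeline consumes.

The generator emulates a GWAS/eQTL colocalization study: an LD-structured
reference genotype panel, GWAS summary statistics with planted association
signals, several eQTL datasets that share a subset of truly colocalized genes
(same signal skeleton, independent noise per dataset), and grouped expression
matrices with planted differential-expression shifts — together with the
ground truth needed for recovery tests.

Model choices
-------------
* LD is modelled as independent AR(1) blocks: within a block, adjacent latent
  haplotype values correlate at ``ld_decay``; blocks are independent. This
  trades realism of long-range LD for closed-form expectations.
* Genotypes follow Hardy-Weinberg: each dosage is the sum of two independent
  haplotypes obtained by thresholding the latent Gaussian at the allele
  frequency quantile. Allele frequencies are Uniform(0.05, 0.5), mirroring
  the MAF >= 5% filters typical of eQTL panels.
* GWAS effects are planted directly on the z-score scale (se = 1): per LD
  block, z ~ MVN(R @ lambda0, R) with R the exact population dosage
  correlation of the thresholded-Gaussian model and lambda0 nonzero only at
  planted causal SNPs. The reference panel is an independent finite-sample
  observation of the same population LD, as in a real study. The pipeline
  consumes summary statistics only, so no individual-level case/control data
  is simulated.
* Each eQTL dataset has its own sample size; the planted per-SNP effect is
  derived per dataset as noncentrality / sqrt(n) so that every validation
  dataset carries the same evidence for the shared colocalized genes.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneModel, GenotypePanel

#: group sizes of the bronchial-epithelium severe-asthma expression cohort
#: (severe asthma / mild-moderate asthma / control) used as defaults
DEFAULT_EXPRESSION_GROUPS = {"SA": 44, "notSA": 72, "Control": 38}

#: default eQTL dataset labels -> sample sizes (monocyte cohort, childhood
#: asthma LCL cohort, HapMap CEU LCL cohort)
DEFAULT_EQTL_DATASETS = {"monocytes": 1490, "lcl_asthma": 400, "lcl_ceu": 87}

_ALLELES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Inconsistent simulation configuration; message names the field."""


@dataclass(frozen=True)
class SyntheticTruth:
    """Fully resolved simulation ground truth.

    ``gwas_noncentrality`` / ``eqtl_noncentrality`` are the expected |z| at a
    planted SNP; the corresponding standardized per-SNP effects are the
    derived properties ``gwas_effect`` and ``eqtl_effect(label)``.
    """

    seed: int
    n_genes: int = 1000
    n_snps: int = 10000
    n_samples_panel: int = 500
    n_gwas: int = 30810
    block_size: int = 10
    ld_decay: float = 0.9
    planted_genes: tuple[str, ...] = ()
    gwas_noncentrality: float = 6.0
    eqtl_noncentrality: float = 6.0
    eqtl_datasets: tuple[tuple[str, int], ...] = tuple(DEFAULT_EQTL_DATASETS.items())
    trans_per_gene: int = 0
    deg_genes: tuple[str, ...] = ()
    deg_shift: float = 3.0
    noise_sd: float = 1.0
    spacing_bp: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)

    # -- layout ------------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    @property
    def snp_ids(self) -> list[str]:
        width = len(str(self.n_snps))
        return [f"rs{i + 1:0{width}d}" for i in range(self.n_snps)]

    @property
    def snp_positions(self) -> np.ndarray:
        return 1 + self.spacing_bp * np.arange(self.n_snps)

    @property
    def snps_per_gene(self) -> int:
        return self.n_snps // self.n_genes

    @property
    def gwas_effect(self) -> float:
        return self.gwas_noncentrality / np.sqrt(self.n_gwas)

    def eqtl_effect(self, dataset_label: str) -> float:
        n = dict(self.eqtl_datasets)[dataset_label]
        return self.eqtl_noncentrality / np.sqrt(n)

    def gene_models(self) -> list[GeneModel]:
        pos = self.snp_positions
        spg = self.snps_per_gene
        return [
            GeneModel(gid, "1", int(pos[i * spg]), int(pos[(i + 1) * spg - 1]))
            for i, gid in enumerate(self.gene_ids)
        ]

    def gene_snp_indices(self, gene_id: str) -> np.ndarray:
        i = self.gene_ids.index(gene_id)
        spg = self.snps_per_gene
        return np.arange(i * spg, (i + 1) * spg)

    def causal_snp_index(self, gene_id: str) -> int:
        idx = self.gene_snp_indices(gene_id)
        return int(idx[len(idx) // 2])

    # -- serialization -----------------------------------------------------
    def to_json(self, path) -> None:
        d = asdict(self)
        d["planted_genes"] = list(self.planted_genes)
        d["deg_genes"] = list(self.deg_genes)
        d["eqtl_datasets"] = dict(self.eqtl_datasets)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["planted_genes"] = tuple(d["planted_genes"])
        d["deg_genes"] = tuple(d["deg_genes"])
        d["eqtl_datasets"] = tuple((k, int(v)) for k, v in d["eqtl_datasets"].items())
        d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


def _stage_rng(truth: SyntheticTruth, tag: str, seed: int | None = None):
    """Deterministic per-stage RNG: truth seed + stable tag hash."""
    base = truth.seed if seed is None else seed
    return np.random.default_rng(
        np.random.SeedSequence([int(base), zlib.crc32(tag.encode())])
    )


def make_truth(seed: int, n_planted: int = 20, n_deg: int | None = None,
               **config) -> SyntheticTruth:
    """Resolve a simulation configuration into a :class:`SyntheticTruth`.

    Planted colocalized genes (and, by default, the same genes as planted
    differentially-expressed genes) are drawn uniformly without replacement
    from the gene universe under the given seed.
    """
    probe = SyntheticTruth(seed=seed, **config)
    for name in ("n_genes", "n_snps", "n_samples_panel", "n_gwas", "block_size"):
        if getattr(probe, name) < 1:
            raise ConfigError(f"{name} must be >= 1")
    if not (0 <= probe.ld_decay < 1):
        raise ConfigError("ld_decay must lie in [0, 1)")
    if probe.n_snps // probe.n_genes < 1:
        raise ConfigError("n_snps must be >= n_genes (at least one SNP per gene)")
    if n_planted < 0 or n_planted > probe.n_genes:
        raise ConfigError(
            f"n_planted ({n_planted}) must lie in [0, n_genes={probe.n_genes}]"
        )
    if n_deg is None:
        n_deg = n_planted
    if n_deg < 0 or n_deg > probe.n_genes:
        raise ConfigError(f"n_deg ({n_deg}) must lie in [0, n_genes={probe.n_genes}]")

    rng = _stage_rng(probe, "truth")
    genes = probe.gene_ids
    planted = tuple(sorted(map(str, rng.choice(genes, size=n_planted,
                                               replace=False)))) \
        if n_planted else ()
    if n_deg == n_planted:
        deg = planted
    else:
        deg = tuple(sorted(map(str, rng.choice(genes, size=n_deg,
                                               replace=False)))) \
            if n_deg else ()
    return SyntheticTruth(seed=seed, planted_genes=planted, deg_genes=deg, **config)


# ---------------------------------------------------------------------------
# Genotype panel
# ---------------------------------------------------------------------------

def allele_frequencies(truth: SyntheticTruth) -> np.ndarray:
    """Population allele frequencies, Uniform over ``truth.maf_range``.

    These are population parameters of the simulated world — a function of
    the truth alone — shared by every panel realization and by the analytic
    LD used to generate GWAS z-scores.
    """
    rng = _stage_rng(truth, "freqs")
    return rng.uniform(*truth.maf_range, size=truth.n_snps)


def _latent_ar1(rng, n_rows: int, n_snps: int, block_size: int,
                rho: float) -> np.ndarray:
    """Latent Gaussian with AR(1) correlation within consecutive blocks."""
    eps = rng.standard_normal((n_rows, n_snps))
    if rho == 0:
        return eps
    x = np.empty_like(eps)
    s = np.sqrt(1.0 - rho * rho)
    for j in range(n_snps):
        if j % block_size == 0:
            x[:, j] = eps[:, j]
        else:
            x[:, j] = rho * x[:, j - 1] + s * eps[:, j]
    return x


def simulate_ld_panel(truth: SyntheticTruth, seed: int | None = None) -> GenotypePanel:
    """Generate the reference genotype panel.

    Two latent haplotypes per sample are drawn per block from an AR(1)
    Gaussian with correlation ``ld_decay`` and thresholded at the allele
    frequency quantile; the dosage is their sum, giving Hardy-Weinberg
    genotypes with within-block LD and independence across blocks.
    """
    rng = _stage_rng(truth, "panel", seed)
    thresh = stats.norm.ppf(allele_frequencies(truth))
    n = truth.n_samples_panel
    latent = _latent_ar1(rng, 2 * n, truth.n_snps, truth.block_size,
                         truth.ld_decay)
    haplotypes = (latent < thresh).astype(np.int8)
    dosages = (haplotypes[:n] + haplotypes[n:]).astype(float)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    return GenotypePanel(sample_ids=sample_ids, snp_ids=truth.snp_ids,
                         dosages=dosages)


def _bvn_lower(h, k, rho, n_quad: int = 48):
    """P(X <= h, Y <= k) for standard bivariate normal, vectorized.

    Uses the Plackett identity d/d(rho) Phi2(h, k; rho) = phi2(h, k; rho),
    integrating the bivariate density over correlation from 0 to rho with
    Gauss-Legendre quadrature — accurate to ~1e-12 for |rho| <= 0.99.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    x, w = np.polynomial.legendre.leggauss(n_quad)
    # nodes on [0, rho] per element: r = rho (x + 1) / 2, weight rho w / 2
    r = rho[..., None] * (x + 1.0) / 2.0
    hh = h[..., None]
    kk = k[..., None]
    one_m_r2 = 1.0 - r * r
    dens = np.exp(-(hh * hh - 2.0 * r * hh * kk + kk * kk)
                  / (2.0 * one_m_r2)) / (2.0 * np.pi * np.sqrt(one_m_r2))
    integral = np.sum(w * dens, axis=-1) * rho / 2.0
    return stats.norm.cdf(h) * stats.norm.cdf(k) + integral


def true_block_ld(truth: SyntheticTruth) -> list[np.ndarray]:
    """Exact population dosage correlation matrix per AR(1) LD block.

    A haplotype carries the allele iff its latent Gaussian falls below the
    frequency quantile, so for SNPs i, j with latent correlation
    rho = ld_decay^|i-j| the allele indicators are thresholded bivariate
    normals and corr(dosage_i, dosage_j) =
    (Phi2(t_i, t_j; rho) - p_i p_j) / sqrt(p_i (1-p_i) p_j (1-p_j)).
    """
    bs = truth.block_size
    n = truth.n_snps
    p = allele_frequencies(truth)
    if truth.ld_decay == 0.0:
        return [np.eye(min(bs, n - s)) for s in range(0, n, bs)]
    t = stats.norm.ppf(p)
    # all within-block (i, j) pairs, i < j, flattened across blocks
    ii, jj = [], []
    for start in range(0, n, bs):
        stop = min(start + bs, n)
        for i in range(start, stop):
            for j in range(i + 1, stop):
                ii.append(i)
                jj.append(j)
    ii = np.asarray(ii, dtype=int)
    jj = np.asarray(jj, dtype=int)
    rho = truth.ld_decay ** (jj - ii)
    p11 = _bvn_lower(t[ii], t[jj], rho)
    corr = (p11 - p[ii] * p[jj]) / np.sqrt(
        p[ii] * (1 - p[ii]) * p[jj] * (1 - p[jj]))
    out = []
    pos = 0
    for start in range(0, n, bs):
        m = min(bs, n - start)
        R = np.eye(m)
        n_pairs = m * (m - 1) // 2
        block_corr = corr[pos:pos + n_pairs]
        pos += n_pairs
        q = 0
        for a in range(m):
            for b in range(a + 1, m):
                R[a, b] = R[b, a] = block_corr[q]
                q += 1
        out.append(R)
    return out


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def simulate_gwas(truth: SyntheticTruth, seed: int | None = None,
                  ridge: float = 1e-6) -> pd.DataFrame:
    """Simulate GWAS summary statistics on the z-score scale.

    Per LD block, z ~ MVN(R @ lambda0, R) where R is the exact population
    dosage correlation (:func:`true_block_ld`) and lambda0 holds
    sqrt(n_gwas) * gwas_effect at planted causal SNPs (the signal propagates
    to LD neighbours through R). beta is reported on the z scale with se = 1;
    p is the two-sided normal tail. Block correlation matrices are
    ridge-regularized by ``ridge`` on the diagonal before the Cholesky
    factorization.
    """
    rng = _stage_rng(truth, "gwas", seed)
    lam0 = np.zeros(truth.n_snps)
    ncp = truth.gwas_noncentrality
    for g in truth.planted_genes:
        lam0[truth.causal_snp_index(g)] = ncp
    blocks = true_block_ld(truth)
    z = np.empty(truth.n_snps)
    bs = truth.block_size
    for bi, R in enumerate(blocks):
        start = bi * bs
        stop = start + R.shape[0]
        mean = R @ lam0[start:stop]
        try:
            L = np.linalg.cholesky(R + ridge * np.eye(R.shape[0]))
        except np.linalg.LinAlgError:
            import warnings
            warnings.warn(f"singular LD block {bi}; increasing ridge")
            L = np.linalg.cholesky(R + 1e-3 * np.eye(R.shape[0]))
        z[start:stop] = mean + L @ rng.standard_normal(R.shape[0])

    pvals = 2 * stats.norm.sf(np.abs(z))
    np.clip(pvals, 1e-300, 1.0, out=pvals)
    ea = rng.choice(_ALLELES, size=truth.n_snps)
    # alternative allele differs from the effect allele
    oa = _ALLELES[(np.searchsorted(_ALLELES, ea) +
                   rng.integers(1, 4, size=truth.n_snps)) % 4]
    return pd.DataFrame({
        "rsid": truth.snp_ids,
        "chrom": "1",
        "pos": truth.snp_positions,
        "ea": ea,
        "oa": oa,
        "beta": z,
        "se": 1.0,
        "pvalue": pvals,
        "n": truth.n_gwas,
    })


# ---------------------------------------------------------------------------
# eQTL datasets
# ---------------------------------------------------------------------------

def simulate_eqtl(truth: SyntheticTruth, panel: GenotypePanel,
                  dataset_label: str, seed: int | None = None) -> pd.DataFrame:
    """Simulate one eQTL dataset.

    The (snp, gene) pair skeleton — each gene against its own cis SNPs, plus
    optional trans SNPs for planted genes — is a function of the truth alone,
    so different dataset labels share the same keys. Planted genes' cis SNP
    z-scores are centered at sqrt(n_eqtl) * eqtl_effect for this dataset's
    sample size; all other pairs are null. Noise is re-drawn independently
    per dataset label.
    """
    labels = dict(truth.eqtl_datasets)
    if dataset_label not in labels:
        raise ConfigError(f"unknown eQTL dataset_label {dataset_label!r}")
    n_eqtl = labels[dataset_label]
    ncp = truth.eqtl_noncentrality
    planted = set(truth.planted_genes)

    # skeleton (shared across labels): truth-seeded rng for trans SNP choice
    skel_rng = _stage_rng(truth, "eqtl-skeleton")
    rows_rsid: list[str] = []
    rows_gene: list[str] = []
    means: list[float] = []
    snp_ids = truth.snp_ids
    for gid in truth.gene_ids:
        idx = truth.gene_snp_indices(gid)
        mu = ncp if gid in planted else 0.0
        for j in idx:
            rows_rsid.append(snp_ids[j])
            rows_gene.append(gid)
            means.append(mu)
        if truth.trans_per_gene and gid in planted:
            far = np.setdiff1d(np.arange(truth.n_snps), idx)
            trans = skel_rng.choice(far, size=truth.trans_per_gene, replace=False)
            for j in trans:
                rows_rsid.append(snp_ids[int(j)])
                rows_gene.append(gid)
                means.append(mu)

    noise_rng = _stage_rng(truth, f"eqtl-noise-{dataset_label}", seed)
    z = np.asarray(means) + noise_rng.standard_normal(len(means))
    pvals = 2 * stats.norm.sf(np.abs(z))
    np.clip(pvals, 1e-300, 1.0, out=pvals)
    return pd.DataFrame({
        "rsid": rows_rsid,
        "gene_id": rows_gene,
        "pvalue": pvals,
        "beta": z / np.sqrt(n_eqtl),
        "dataset_label": dataset_label,
    })


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def simulate_expression(truth: SyntheticTruth,
                        groups: dict[str, int] | None = None,
                        shifted_groups: tuple[str, ...] = ("SA",),
                        seed: int | None = None) -> ExpressionMatrix:
    """Simulate a gene x sample expression matrix with group labels.

    Baseline expression is Gaussian noise with sd ``truth.noise_sd``; the
    planted differentially-expressed genes (``truth.deg_genes``) get
    ``truth.deg_shift`` added in the ``shifted_groups`` samples.
    """
    if groups is None:
        groups = dict(DEFAULT_EXPRESSION_GROUPS)
    if len(groups) < 2:
        raise ConfigError("need >= 2 expression groups")
    for label, size in groups.items():
        if size < 2:
            raise ConfigError(f"group {label!r} has size {size} < 2")
    unknown = [g for g in shifted_groups if g not in groups]
    if unknown:
        raise ConfigError(f"shifted_groups not in groups: {unknown}")

    rng = _stage_rng(truth, "expression", seed)
    sample_ids, labels = [], []
    for label, size in groups.items():
        for k in range(size):
            sample_ids.append(f"{label}_{k + 1:03d}")
            labels.append(label)
    n_samples = len(sample_ids)
    values = rng.normal(0.0, truth.noise_sd, size=(truth.n_genes, n_samples))
    if truth.deg_genes and truth.deg_shift != 0:
        gene_pos = {g: i for i, g in enumerate(truth.gene_ids)}
        shifted_cols = np.array([lbl in set(shifted_groups) for lbl in labels])
        for g in truth.deg_genes:
            values[gene_pos[g], shifted_cols] += truth.deg_shift
    df = pd.DataFrame(values, index=truth.gene_ids, columns=sample_ids)
    return ExpressionMatrix(values=df,
                            groups=pd.Series(labels, index=sample_ids))
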