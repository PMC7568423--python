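"""Resampling machinery: gene-set overlap permutation test, random-phenotype
null GWAS negative control, and the threshold-profile overlap comparison.

The overlap permutation test asks whether two significant-gene lists share
more genes than random lists of the same sizes drawn from the background.
The null GWAS reuses the reference genotype panel with a randomly assigned
binary phenotype: any downstream "signal" it yields measures artefact, not
biology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import GenotypePanel


@dataclass
class OverlapPermutationResult:
    observed_overlap: int
    list_a_size: int
    list_b_size: int
    background_size: int
    B: int
    count_ge: int
    empirical_p: float
    seed: int | None


@dataclass
class NullGwasResult:
    """Per-SNP association p-values from a randomly assigned phenotype."""

    snp_ids: list[str]
    pvalues: np.ndarray
    chi2: np.ndarray
    monomorphic: np.ndarray  # bool flags; such SNPs carry p = 1
    n_cases: int
    seed: int | None


def overlap_permutation_test(list_a, list_b, background, B: int = 100_000,
                             seed: int | None = None,
                             add_one: bool = True) -> OverlapPermutationResult:
    """Empirical p for the overlap of two gene lists against random draws.

    Each replicate draws |list_a| genes uniformly without replacement from
    the background and counts the overlap with list_b. With the default
    add-one correction, empirical_p = (1 + #{overlap >= observed}) / (B + 1),
    which never returns 0; a result below the resolution is reported as the
    floor 1/(B+1). ``add_one=False`` gives the raw proportion.
    """
    a, b, bg = set(list_a), set(list_b), list(dict.fromkeys(background))
    bg_set = set(bg)
    if B < 1:
        raise ValueError("B must be >= 1")
    stray = sorted((a | b) - bg_set)
    if stray:
        raise ValueError(f"genes not in background: {stray[:10]}")
    observed = len(a & b)
    mask = np.array([g in b for g in bg])
    rng = np.random.default_rng(seed)
    n_a = len(a)
    count_ge = 0
    for _ in range(B):
        draw = rng.choice(len(bg), size=n_a, replace=False)
        if int(mask[draw].sum()) >= observed:
            count_ge += 1
    if add_one:
        p = (1.0 + count_ge) / (B + 1.0)
    else:
        p = count_ge / B
    return OverlapPermutationResult(
        observed_overlap=observed, list_a_size=n_a, list_b_size=len(b),
        background_size=len(bg), B=B, count_ge=count_ge,
        empirical_p=float(p), seed=seed,
    )


def null_gwas(panel: GenotypePanel, n_cases: int,
              seed: int | None = None) -> NullGwasResult:
    """Random-phenotype association scan on the genotype panel.

    The binary trait is assigned by a seeded permutation preserving the case
    count; each SNP is tested with the additive-dosage score test (the
    Cochran-Armitage-style 1-df chi-square N * r^2 of the trait-dosage
    correlation), asymptotically equivalent to per-SNP logistic regression
    under the null. Monomorphic SNPs carry p = 1 and are flagged.
    """
    n = panel.n_samples
    if not (0 < n_cases < n):
        raise ValueError(f"n_cases must lie in (0, {n})")
    rng = np.random.default_rng(seed)
    y = np.zeros(n)
    y[rng.permutation(n)[:n_cases]] = 1.0

    G = panel.dosages
    yc = y - y.mean()
    gc = G - G.mean(axis=0)
    g_ss = (gc * gc).sum(axis=0)
    mono = g_ss == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (yc @ G) / np.sqrt((yc @ yc) * g_ss)
    chi2 = np.where(mono, 0.0, n * r * r)
    pvals = np.where(mono, 1.0, stats.chi2.sf(chi2, df=1))
    return NullGwasResult(snp_ids=list(panel.snp_ids), pvalues=pvals,
                          chi2=chi2, monomorphic=mono, n_cases=n_cases,
                          seed=seed)


def genomic_inflation(pvalues) -> float:
    """lambda_GC = median(chi2_1 quantile of p) / 0.455 (approx 1 under the null)."""
    p = np.asarray(pvalues, dtype=float)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def threshold_overlap_profile(query_genes, result_table: dict,
                              thresholds=(0.05, 0.01, 0.001, 0.0001)
                              ) -> dict[float, float]:
    """Fraction of the query significant in a gene->p table per threshold.

    Run once on the real-GWAS table and once on the null-control table, the
    two profiles contrast genuine enrichment against chance overlap.
    Thresholds must be strictly decreasing, each in (0, 1).
    """
    query = set(query_genes)
    if not query:
        raise ValueError("empty query gene set")
    ts = list(thresholds)
    if any(not (0 < t < 1) for t in ts):
        raise ValueError("thresholds must lie in (0, 1)")
    if any(ts[i] <= ts[i + 1] for i in range(len(ts) - 1)):
        raise ValueError("thresholds must be strictly decreasing")
    out = {}
    for t in ts:
        sig = {g for g, p in result_table.items() if p <= t}
        out[t] = len(query & sig) / len(query)
    return out
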