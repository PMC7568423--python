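"""GWAS-eQTL Bayesian integration: eSNP scoring and per-gene log Bayes factors.

For each gene, SNPs significantly associated with its expression (eSNPs) are
scored against the GWAS with an approximate log Bayes factor on the z-score
scale,

    ln BF(z; W) = 1/2 ln(1 / (1 + W)) + (z^2 / 2) * (W / (1 + W)),

the Wakefield-style asymptotic Bayes factor with prior effect variance W on a
unit-se standardized effect. An eSNP whose GWAS signal is strong contributes
a positive score; a GWAS-null eSNP contributes a negative score; SNPs that
are not eSNPs contribute nothing. The gene score (LBF) is the sum over its
LD-pruned eSNPs; significance comes from a Monte-Carlo "simulated" p-value
obtained by permuting the genome-wide GWAS z pool over SNPs, and genes are
adjusted by Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GenotypePanel


class Scenario(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    IGNORED = "ignored"


@dataclass(frozen=True)
class EsnpScore:
    """One eSNP's contribution to a gene's log Bayes factor."""

    rsid: str
    gene_id: str
    p_eqtl: float
    p_gwas: float
    z_gwas: float  # |z| implied by the two-sided GWAS p
    log_bf: float  # natural-log Bayes factor contribution (signed)
    scenario: Scenario


@dataclass
class GeneLbfResult:
    """Aggregated gene score: sum of retained eSNP log Bayes factors."""

    gene_id: str
    lbf: float
    n_esnps: int
    contributions: list[EsnpScore]
    simulated_p: float | None = None
    bh_q: float | None = None


def z_from_p(p) -> np.ndarray:
    """|z| implied by a two-sided normal p-value."""
    return stats.norm.isf(np.asarray(p, dtype=float) / 2.0)


def snp_log_bayes_factor(z_gwas, prior_w: float = 0.1):
    """ln BF(association vs null) for a unit-se z-score under prior variance W.

    Strictly increasing in z^2 and negative at z = 0; the sign realizes the
    positive/negative scoring of GWAS-significant vs GWAS-null eSNPs.
    """
    if prior_w <= 0:
        raise ValueError("prior_w must be > 0")
    z = np.asarray(z_gwas, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite z_gwas")
    shrink = prior_w / (1.0 + prior_w)
    out = 0.5 * np.log(1.0 / (1.0 + prior_w)) + 0.5 * z * z * shrink
    return float(out) if np.isscalar(z_gwas) else out


def identify_esnps(eqtl: pd.DataFrame, p_threshold: float = 1e-4) -> pd.DataFrame:
    """eSNPs: (rsid, gene_id) pairs with eQTL p <= threshold (inclusive).

    Duplicated pairs are collapsed keeping the smallest p.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must lie in (0, 1)")
    if len(eqtl) == 0:
        return pd.DataFrame(columns=["rsid", "gene_id", "p_eqtl"])
    hits = eqtl.loc[eqtl["pvalue"] <= p_threshold, ["rsid", "gene_id", "pvalue"]]
    hits = (hits.sort_values("pvalue")
                .drop_duplicates(subset=["rsid", "gene_id"], keep="first")
                .rename(columns={"pvalue": "p_eqtl"}))
    return hits.reset_index(drop=True)


def prune_esnps_by_ld(esnps: pd.DataFrame, panel: GenotypePanel,
                      r2_max: float = 0.8) -> pd.DataFrame:
    """Greedy LD pruning of one gene's eSNPs.

    Sorted by eQTL p ascending, an eSNP is kept iff its panel r^2 with every
    already-kept eSNP is <= r2_max. SNPs absent from the panel are kept with
    a warning (their LD is unknown). Prevents LD-duplicated signals from
    being double counted in the gene score.
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must lie in (0, 1]")
    if len(esnps) <= 1:
        return esnps.reset_index(drop=True)
    lookup = {s: i for i, s in enumerate(panel.snp_ids)}
    order = esnps.sort_values(["p_eqtl", "rsid"], kind="mergesort")
    kept_rows = []
    kept_cols: list[np.ndarray] = []
    for _, row in order.iterrows():
        col_idx = lookup.get(row["rsid"])
        if col_idx is None:
            warnings.warn(f"eSNP {row['rsid']} absent from panel; kept unpruned")
            kept_rows.append(row)
            continue
        col = panel.dosages[:, col_idx]
        if col.std() == 0:
            kept_rows.append(row)
            continue
        ok = True
        for other in kept_cols:
            r = np.corrcoef(col, other)[0, 1]
            if np.isfinite(r) and r * r > r2_max:
                ok = False
                break
        if ok:
            kept_rows.append(row)
            kept_cols.append(col)
    return pd.DataFrame(kept_rows).reset_index(drop=True)


def score_esnps(esnps: pd.DataFrame, gwas: pd.DataFrame,
                prior_w: float = 0.1) -> list[EsnpScore]:
    """Attach GWAS z and log BF to eSNP pairs; pairs whose SNP is missing
    from the GWAS cannot be scored and are dropped with a warning."""
    pmap = gwas.set_index("rsid")["pvalue"]
    scores = []
    missing = []
    for _, row in esnps.iterrows():
        p_gwas = pmap.get(row["rsid"])
        if p_gwas is None:
            missing.append(row["rsid"])
            continue
        z = float(z_from_p(p_gwas))
        lbf = snp_log_bayes_factor(z, prior_w)
        scenario = Scenario.POSITIVE if lbf > 0 else Scenario.NEGATIVE
        scores.append(EsnpScore(rsid=row["rsid"], gene_id=row["gene_id"],
                                p_eqtl=float(row["p_eqtl"]),
                                p_gwas=float(p_gwas), z_gwas=z,
                                log_bf=float(lbf), scenario=scenario))
    if missing:
        warnings.warn(f"{len(missing)} eSNPs absent from the GWAS were dropped")
    return scores


def gene_lbf(gene_id: str, scores: list[EsnpScore]) -> GeneLbfResult:
    """Sum a gene's pruned eSNP scores into its LBF.

    Genes with zero eSNPs receive no score at all and must be excluded from
    results by the caller (handled by :func:`run_bayes`).
    """
    bad = [s.rsid for s in scores if s.gene_id != gene_id]
    if bad:
        raise ValueError(f"scores for foreign gene(s) passed to {gene_id}: {bad}")
    lbf = float(sum(s.log_bf for s in scores))
    return GeneLbfResult(gene_id=gene_id, lbf=lbf, n_esnps=len(scores),
                         contributions=list(scores))


def simulated_gene_pvalues(results: list[GeneLbfResult], gwas: pd.DataFrame,
                           B: int = 1000, seed: int | None = None,
                           prior_w: float = 0.1) -> list[GeneLbfResult]:
    """Monte-Carlo gene p-values under permutation of the GWAS z pool.

    Each replicate reassigns the genome-wide z-scores to SNPs by a uniform
    random permutation (the eQTL/eSNP structure stays fixed) and recomputes
    every gene's LBF; simulated_p = (1 + #{null lbf >= observed}) / (B + 1).
    """
    if B < 100:
        raise ValueError("B must be >= 100 (tail too unstable below that)")
    rng = np.random.default_rng(seed)
    z2 = z_from_p(gwas["pvalue"].to_numpy()) ** 2
    n_snps = len(z2)
    pos = {s: i for i, s in enumerate(gwas["rsid"])}

    flat_idx: list[int] = []
    boundaries = [0]
    for res in results:
        flat_idx.extend(pos[c.rsid] for c in res.contributions)
        boundaries.append(len(flat_idx))
    flat_idx_arr = np.asarray(flat_idx, dtype=int)
    starts = np.asarray(boundaries[:-1], dtype=int)

    shrink = prior_w / (1.0 + prior_w)
    const = 0.5 * np.log(1.0 / (1.0 + prior_w))
    observed = np.array([r.lbf for r in results])
    k = np.diff(boundaries)

    count_ge = np.zeros(len(results), dtype=int)
    for _ in range(B):
        z2p = z2[rng.permutation(n_snps)]
        sums = np.add.reduceat(z2p[flat_idx_arr], starts) if len(flat_idx_arr) \
            else np.zeros(len(results))
        # reduceat yields garbage for empty segments; genes always have >= 1 eSNP
        null_lbf = k * const + 0.5 * shrink * sums
        count_ge += null_lbf >= observed - 1e-12
    pvals = (1.0 + count_ge) / (B + 1.0)
    for res, p in zip(results, pvals):
        res.simulated_p = float(p)
    return results


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_bayes(gwas: pd.DataFrame, eqtl: pd.DataFrame, panel: GenotypePanel,
              esnp_p: float = 1e-4, prior_w: float = 0.1, r2_max: float = 0.8,
              B: int = 1000, seed: int | None = None) -> list[GeneLbfResult]:
    """Full integration for one eQTL dataset: eSNPs -> prune -> LBF -> p/q.

    Returns results for genes with >= 1 scored eSNP, sorted by simulated p
    then descending LBF.
    """
    esnps = identify_esnps(eqtl, p_threshold=esnp_p)
    results: list[GeneLbfResult] = []
    for gene_id, grp in esnps.groupby("gene_id", sort=True):
        pruned = prune_esnps_by_ld(grp, panel, r2_max=r2_max)
        scores = score_esnps(pruned, gwas, prior_w=prior_w)
        if not scores:
            continue  # no scorable eSNP: the gene receives no score
        results.append(gene_lbf(gene_id, scores))
    if not results:
        return results
    simulated_gene_pvalues(results, gwas, B=B, seed=seed, prior_w=prior_w)
    qs = bh_adjust([r.simulated_p for r in results])
    for r, q in zip(results, qs):
        r.bh_q = float(q)
    results.sort(key=lambda r: (r.simulated_p, -r.lbf))
    return results


def results_to_frame(results: list[GeneLbfResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "gene_id": [r.gene_id for r in results],
        "lbf": [r.lbf for r in results],
        "n_esnps": [r.n_esnps for r in results],
        "simulated_p": [r.simulated_p for r in results],
        "bh_q": [r.bh_q for r in results],
    })


def contributions_to_records(results: list[GeneLbfResult]) -> list[dict]:
    """Per-eSNP contributions in a JSON-serializable form."""
    out = []
    for r in results:
        for c in r.contributions:
            out.append({
                "gene_id": c.gene_id, "rsid": c.rsid, "p_eqtl": c.p_eqtl,
                "p_gwas": c.p_gwas, "z_gwas": c.z_gwas, "log_bf": c.log_bf,
                "scenario": c.scenario.value,
            })
    return out
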