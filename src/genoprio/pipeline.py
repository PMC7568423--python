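"""End-to-end orchestration of the synthetic prioritization study.

One call simulates the study inputs (reference panel, GWAS summary
statistics, several eQTL datasets), runs the Bayesian integration per eQTL
dataset, the LD-aware gene-based GWAS test, the random-phenotype negative
control, and the cross-analysis consensus filter, returning everything a
recovery or calibration analysis needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bayes, consensus, gene_based, resampling, synthetic
from .io import GenotypePanel
from .synthetic import SyntheticTruth


@dataclass
class StudyResult:
    truth: SyntheticTruth
    panel: GenotypePanel
    gwas: pd.DataFrame
    eqtl: dict[str, pd.DataFrame]
    bayes_results: dict[str, list[bayes.GeneLbfResult]]
    gene_based_results: list[gene_based.GeneBasedResult]
    null_gwas_result: resampling.NullGwasResult
    null_gene_based: dict[str, float]
    consensus_rows: list[consensus.ConsensusRow]
    venn_counts: dict[str, int] | None

    def bayes_pmap(self, label: str) -> dict[str, float]:
        return {r.gene_id: r.simulated_p for r in self.bayes_results[label]}

    def gene_based_pmap(self) -> dict[str, float]:
        return {r.gene_id: r.pvalue for r in self.gene_based_results}


def null_gwas_gene_pvalues(null_result: resampling.NullGwasResult,
                           truth: SyntheticTruth, panel: GenotypePanel,
                           window_bp: int = 20000) -> dict[str, float]:
    """Gene-level p-values of the negative control.

    The random-phenotype per-SNP chi-squares are fed through the same
    LD-aware gene-based test as the real GWAS (|z| = sqrt(chi2); the gene
    statistic uses z^2 only).
    """
    fake = pd.DataFrame({
        "rsid": null_result.snp_ids,
        "chrom": "1",
        "pos": truth.snp_positions,
        "ea": "A", "oa": "G",
        "beta": np.sqrt(null_result.chi2),
        "se": 1.0,
        "pvalue": np.clip(null_result.pvalues, 1e-300, 1.0),
        "n": panel.n_samples,
    })
    res = gene_based.run_gene_based(fake, truth.gene_models(), panel,
                                    window_bp=window_bp)
    return {r.gene_id: r.pvalue for r in res}


def run_synthetic_study(truth: SyntheticTruth, *, B: int = 200,
                        alpha: float = 0.05, esnp_p: float = 1e-4,
                        prior_w: float = 0.1, r2_max: float = 0.8,
                        window_bp: int = 20000,
                        n_cases: int | None = None,
                        catalog: set | None = None) -> StudyResult:
    """Simulate and analyse one full study under the given ground truth.

    ``B`` is the Monte-Carlo replicate count for the simulated gene
    p-values; ``alpha`` the per-analysis inclusion level of the consensus
    filter; ``n_cases`` the case count of the random-phenotype negative
    control (default: half the panel).
    """
    panel = synthetic.simulate_ld_panel(truth)
    gwas = synthetic.simulate_gwas(truth)
    labels = [lbl for lbl, _ in truth.eqtl_datasets]
    eqtl = {lbl: synthetic.simulate_eqtl(truth, panel, lbl) for lbl in labels}

    bayes_results = {}
    for i, lbl in enumerate(labels):
        bayes_results[lbl] = bayes.run_bayes(
            gwas, eqtl[lbl], panel, esnp_p=esnp_p, prior_w=prior_w,
            r2_max=r2_max, B=B, seed=truth.seed * 97 + i,
        )

    gb = gene_based.run_gene_based(gwas, truth.gene_models(), panel,
                                   window_bp=window_bp)

    if n_cases is None:
        n_cases = panel.n_samples // 2
    null_res = resampling.null_gwas(panel, n_cases=n_cases,
                                    seed=truth.seed * 131 + 7)
    null_gene = null_gwas_gene_pvalues(null_res, truth, panel,
                                       window_bp=window_bp)

    results_maps = {lbl: {r.gene_id: r.simulated_p for r in bayes_results[lbl]}
                    for lbl in labels}
    results_maps["gene_based"] = {r.gene_id: r.pvalue for r in gb}
    rows = consensus.build_consensus_table(results_maps, alpha=alpha,
                                           null_control=null_gene,
                                           catalog=catalog)
    sig_sets = {lbl: {g for g, p in pm.items() if p < alpha}
                for lbl, pm in results_maps.items()}
    _, venn = consensus.intersect_results(sig_sets)

    return StudyResult(truth=truth, panel=panel, gwas=gwas, eqtl=eqtl,
                       bayes_results=bayes_results, gene_based_results=gb,
                       null_gwas_result=null_res, null_gene_based=null_gene,
                       consensus_rows=rows, venn_counts=venn)


def recovery_metrics(study: StudyResult, top_k: int = 20) -> dict[str, float]:
    """Planted-gene recovery summary for one study.

    * ``top{k}_planted_<label>``: planted genes among the top-k by LBF.
    * ``consensus_recall``: fraction of planted genes in the consensus table.
    * ``consensus_fpr``: fraction of non-planted genes in the consensus table.
    """
    truth = study.truth
    planted = set(truth.planted_genes)
    out: dict[str, float] = {}
    for lbl, res in study.bayes_results.items():
        top = sorted(res, key=lambda r: -r.lbf)[:top_k]
        out[f"top{top_k}_planted_{lbl}"] = sum(r.gene_id in planted for r in top)
    consensus_genes = {r.gene_id for r in study.consensus_rows}
    out["consensus_recall"] = (len(consensus_genes & planted) / len(planted)
                               if planted else float("nan"))
    non_planted = truth.n_genes - len(planted)
    out["consensus_fpr"] = (len(consensus_genes - planted) / non_planted
                            if non_planted else float("nan"))
    return out
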