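"""Tests of the GWAS-eQTL Bayesian integration: closed-form Bayes factors,
eSNP selection and pruning invariants, and the Monte-Carlo gene p-value."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genoprio import bayes, synthetic
from genoprio.bayes import Scenario


def _gwas_frame(rsids, pvalues):
    n = len(rsids)
    return pd.DataFrame({
        "rsid": rsids, "chrom": "1", "pos": np.arange(1, n + 1),
        "ea": "A", "oa": "G",
        "beta": bayes.z_from_p(pvalues), "se": 1.0,
        "pvalue": pvalues, "n": 1000,
    })


class TestLogBayesFactor:
    def test_closed_form_against_density_ratio(self):
        """ln BF equals ln[ N(z; 0, 1+W) / N(z; 0, 1) ], the marginal
        likelihood ratio it approximates, to 1e-12."""
        for z in [0.0, 1.3, 3.2, 6.0]:
            for w in [0.05, 0.1, 0.5]:
                expected = (stats.norm.logpdf(z, scale=math.sqrt(1 + w))
                            - stats.norm.logpdf(z))
                assert bayes.snp_log_bayes_factor(z, w) == pytest.approx(
                    expected, abs=1e-12)

    def test_sign_structure(self):
        # negative at z=0, crosses zero, positive for strong signals
        assert bayes.snp_log_bayes_factor(0.0) < 0
        assert bayes.snp_log_bayes_factor(6.0) > 0
        # strictly increasing in |z|
        zs = np.linspace(0, 8, 50)
        vals = bayes.snp_log_bayes_factor(zs)
        assert np.all(np.diff(vals) > 0)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError, match="prior_w"):
            bayes.snp_log_bayes_factor(1.0, prior_w=0.0)

    def test_z_from_p_inverts_two_sided_p(self, rng):
        z = rng.uniform(0.1, 8, size=20)
        p = 2 * stats.norm.sf(z)
        assert np.allclose(bayes.z_from_p(p), z)


class TestIdentifyEsnps:
    def test_threshold_inclusive(self):
        eq = pd.DataFrame({"rsid": ["a", "b", "c"], "gene_id": "G1",
                           "pvalue": [1e-4, 1.0000001e-4, 1e-5],
                           "beta": 0.0, "dataset_label": "lab"})
        hits = bayes.identify_esnps(eq, p_threshold=1e-4)
        assert set(hits["rsid"]) == {"a", "c"}

    def test_duplicates_keep_min_p(self):
        eq = pd.DataFrame({"rsid": ["a", "a"], "gene_id": "G1",
                           "pvalue": [1e-5, 1e-8],
                           "beta": 0.0, "dataset_label": "lab"})
        hits = bayes.identify_esnps(eq)
        assert len(hits) == 1
        assert hits.loc[0, "p_eqtl"] == 1e-8

    def test_empty_input(self):
        assert len(bayes.identify_esnps(pd.DataFrame(
            columns=["rsid", "gene_id", "pvalue"]))) == 0


def _panel_from_dosages(dosages, snp_ids):
    from genoprio.io import GenotypePanel
    return GenotypePanel(
        sample_ids=[f"s{i}" for i in range(dosages.shape[0])],
        snp_ids=snp_ids, dosages=np.asarray(dosages, dtype=float))


class TestPruning:
    def test_matches_independent_greedy_reimplementation(self, small_truth,
                                                         small_panel,
                                                         small_eqtl):
        esnps = bayes.identify_esnps(small_eqtl)
        lookup = {s: i for i, s in enumerate(small_panel.snp_ids)}
        for gene_id, grp in esnps.groupby("gene_id"):
            pruned = bayes.prune_esnps_by_ld(grp, small_panel, r2_max=0.8)
            # oracle: literal greedy scan in (p, rsid) order
            expect = []
            for _, row in grp.sort_values(["p_eqtl", "rsid"]).iterrows():
                col = small_panel.dosages[:, lookup[row["rsid"]]]
                if all(np.corrcoef(col,
                                   small_panel.dosages[:, lookup[k]])[0, 1] ** 2
                       <= 0.8 for k in expect):
                    expect.append(row["rsid"])
            assert list(pruned["rsid"]) == expect

    def test_perfect_duplicate_pruned(self):
        dos = np.array([[0, 0, 2.0], [1, 1, 1], [2, 2, 0], [0, 0, 1]])
        panel = _panel_from_dosages(dos, ["a", "b", "c"])
        esnps = pd.DataFrame({"rsid": ["a", "b", "c"], "gene_id": "G1",
                              "p_eqtl": [1e-8, 1e-6, 1e-5]})
        pruned = bayes.prune_esnps_by_ld(esnps, panel, r2_max=0.8)
        assert list(pruned["rsid"]) == ["a", "c"]

    def test_snp_missing_from_panel_kept_with_warning(self):
        dos = np.array([[0.0], [1], [2], [1]])
        panel = _panel_from_dosages(dos, ["a"])
        esnps = pd.DataFrame({"rsid": ["a", "zz"], "gene_id": "G1",
                              "p_eqtl": [1e-8, 1e-6]})
        with pytest.warns(UserWarning, match="zz"):
            pruned = bayes.prune_esnps_by_ld(esnps, panel)
        assert set(pruned["rsid"]) == {"a", "zz"}


class TestScoringScenarios:
    def test_positive_negative_ignored(self):
        gwas = _gwas_frame(["hit", "nullsnp", "other"], [1e-8, 0.9, 0.5])
        esnps = pd.DataFrame({"rsid": ["hit", "nullsnp"], "gene_id": "G1",
                              "p_eqtl": [1e-6, 1e-6]})
        scores = bayes.score_esnps(esnps, gwas)
        by = {s.rsid: s for s in scores}
        assert by["hit"].scenario is Scenario.POSITIVE
        assert by["hit"].log_bf > 0
        assert by["nullsnp"].scenario is Scenario.NEGATIVE
        assert by["nullsnp"].log_bf < 0
        assert "other" not in by  # not an eSNP: contributes nothing

    def test_missing_from_gwas_dropped_with_warning(self):
        gwas = _gwas_frame(["a"], [0.01])
        esnps = pd.DataFrame({"rsid": ["a", "gone"], "gene_id": "G1",
                              "p_eqtl": [1e-6, 1e-6]})
        with pytest.warns(UserWarning, match="absent from the GWAS"):
            scores = bayes.score_esnps(esnps, gwas)
        assert [s.rsid for s in scores] == ["a"]

    def test_gene_lbf_is_sum_and_rejects_foreign_scores(self):
        gwas = _gwas_frame(["a", "b"], [1e-6, 0.2])
        esnps = pd.DataFrame({"rsid": ["a", "b"], "gene_id": "G1",
                              "p_eqtl": [1e-6, 1e-5]})
        scores = bayes.score_esnps(esnps, gwas)
        res = bayes.gene_lbf("G1", scores)
        assert res.lbf == pytest.approx(sum(s.log_bf for s in scores))
        with pytest.raises(ValueError, match="foreign"):
            bayes.gene_lbf("G2", scores)


class TestSimulatedP:
    def test_tiny_pool_matches_exact_enumeration(self):
        """One gene, one eSNP, pool of 3 z-scores: the permutation null is a
        uniform draw from the pool, so the exact p is computable by hand and
        the B=20000 Monte-Carlo estimate must sit within 4 binomial SEs."""
        gwas = _gwas_frame(["a", "b", "c"], [0.001, 0.2, 0.9])
        esnps = pd.DataFrame({"rsid": ["b"], "gene_id": "G1",
                              "p_eqtl": [1e-6]})
        scores = bayes.score_esnps(esnps, gwas)
        res = bayes.gene_lbf("G1", scores)
        B = 20000
        out = bayes.simulated_gene_pvalues([res], gwas, B=B, seed=11)
        # observed lbf = lbf(z_b); null draws z uniformly from {a,b,c};
        # lbf is increasing in |z| so P(null >= obs) = P(p_null <= 0.2) = 2/3
        exact = 2.0 / 3.0
        se = math.sqrt(exact * (1 - exact) / B)
        assert abs(out[0].simulated_p - exact) < 4 * se + 1 / B

    def test_null_calibration_uniform(self):
        """Under an exchangeable z pool (no LD) the simulated p of null genes
        is uniform: KS p > 0.01 and type-1 rate within 0.05 +/- 0.02."""
        t = synthetic.make_truth(seed=301, n_planted=500, n_genes=500,
                                 n_snps=5000, n_samples_panel=300,
                                 ld_decay=0.0, gwas_noncentrality=0.0)
        panel = synthetic.simulate_ld_panel(t)
        gwas = synthetic.simulate_gwas(t)
        eqtl = synthetic.simulate_eqtl(t, panel, "monocytes")
        results = bayes.run_bayes(gwas, eqtl, panel, B=500, seed=17)
        assert len(results) >= 300
        ps = np.array([r.simulated_p for r in results])
        assert stats.kstest(ps, "uniform").pvalue > 0.01
        assert abs((ps < 0.05).mean() - 0.05) < 0.02

    def test_b_too_small_rejected(self):
        gwas = _gwas_frame(["a"], [0.5])
        res = bayes.gene_lbf("G1", [])
        with pytest.raises(ValueError, match="B"):
            bayes.simulated_gene_pvalues([res], gwas, B=50)


class TestBhAdjust:
    def test_hand_example(self):
        q = bayes.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=200)
        q = bayes.bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bayes.bh_adjust([0.5, 0.0])


class TestRunBayes:
    def test_planted_genes_top_ranked(self, small_truth, small_panel,
                                      small_gwas, small_eqtl):
        results = bayes.run_bayes(small_gwas, small_eqtl, small_panel,
                                  B=300, seed=5)
        top = {r.gene_id for r in results[:len(small_truth.planted_genes)]}
        assert set(small_truth.planted_genes) <= top

    def test_deterministic_under_seed(self, small_panel, small_gwas,
                                      small_eqtl):
        a = bayes.run_bayes(small_gwas, small_eqtl, small_panel, B=200, seed=3)
        b = bayes.run_bayes(small_gwas, small_eqtl, small_panel, B=200, seed=3)
        assert bayes.results_to_frame(a).equals(bayes.results_to_frame(b))

    def test_frame_and_records_round(self, small_panel, small_gwas,
                                     small_eqtl):
        results = bayes.run_bayes(small_gwas, small_eqtl, small_panel,
                                  B=200, seed=3)
        df = bayes.results_to_frame(results)
        assert df["simulated_p"].between(0, 1).all()
        recs = bayes.contributions_to_records(results)
        assert {r["scenario"] for r in recs} <= {"positive", "negative"}
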