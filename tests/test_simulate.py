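"""Determinism, range invariants and effect-recovery of the generators."""

import numpy as np
import pandas as pd
import pytest

from adipomethyl import ewas, simulate
from adipomethyl.simulate import (CohortConfig, GeneticScenarioConfig,
                                  generate_annotation, generate_cohort,
                                  generate_consortium,
                                  generate_expression,
                                  generate_genetic_scenario)


class TestGenerateCohort:
    def test_same_seed_is_bit_identical(self):
        cfg = CohortConfig(n_samples=80, n_cpgs=50, seed=3)
        a, ta = generate_cohort(cfg)
        b, tb = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.beta, b.beta)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)
        pd.testing.assert_frame_equal(ta.effects, tb.effects)

    def test_beta_in_range_and_low_clipping(self):
        ds, _ = generate_cohort(CohortConfig(n_samples=300, n_cpgs=400, seed=1))
        v = ds.beta.to_numpy()
        assert v.min() >= 0.0 and v.max() <= 1.0
        assert ds.clip_fraction < 0.01

    def test_cell_proportions_valid(self):
        ds, _ = generate_cohort(CohortConfig(n_samples=200, n_cpgs=10, seed=2))
        main = ds.covariates[simulate.MAIN_CELLS]
        ext = ds.covariates[simulate.EXTENDED_CELLS]
        assert ((main >= 0) & (main <= 1)).all().all()
        # implicit granulocyte reference: included proportions sum below 1
        assert (main.sum(axis=1) < 1).all()
        assert (ext.sum(axis=1) < 1).all()
        # the five aggregates and the extended set describe the same blood
        agg_b = ds.covariates["Bmem"] + ds.covariates["Bnv"]
        assert np.allclose(agg_b, ds.covariates["B"])

    def test_infeasible_noise_raises(self):
        with pytest.raises(simulate.GenerationError):
            generate_cohort(CohortConfig(n_samples=60, n_cpgs=30,
                                         noise_sd=5.0, seed=0))

    def test_null_config_slopes_center_on_zero(self):
        cfg = CohortConfig(n_samples=400, n_cpgs=300, frac_causal=0.0, seed=5)
        ds, truth = generate_cohort(cfg)
        assert truth.causal_ids() == []
        rec = ewas.run_model(ds, ewas.ModelSpec())
        z = rec["beta"] / rec["se"]
        assert abs(z.mean()) < 3.0 / np.sqrt(len(z))

    def test_noiseless_limit_recovers_planted_slope(self):
        cfg = CohortConfig(n_samples=150, n_cpgs=20, frac_causal=0.05,
                           noise_sd=1e-8, intercept_shift_sd=0.0, seed=9)
        ds, truth = generate_cohort(cfg)
        rec = ewas.run_model(ds, ewas.ModelSpec()).set_index("cpg_id")
        for _, row in truth.effects[truth.effects["true_beta"] != 0].iterrows():
            assert rec.loc[row["cpg_id"], "beta"] == pytest.approx(
                row["true_beta"], abs=1e-6)

    def test_slope_estimates_unbiased_over_seeds(self):
        # Monte-Carlo oracle: mean fitted-minus-true slope across causal
        # CpGs stays within ±0.002 of zero over 20 replicate cohorts
        errs = []
        for seed in range(20):
            cfg = CohortConfig(n_samples=500, n_cpgs=1000, frac_causal=0.05,
                               effect_size_sd=0.01, seed=seed)
            ds, truth = generate_cohort(cfg)
            rec = ewas.run_model(ds, ewas.ModelSpec()).set_index("cpg_id")
            eff = truth.effects[truth.effects["true_beta"] != 0]
            errs.append(np.mean(rec.loc[eff["cpg_id"], "beta"].to_numpy()
                                - eff["true_beta"].to_numpy()))
        assert abs(np.mean(errs)) < 0.002


class TestConsortium:
    def test_published_sizes_total(self):
        configs = simulate.default_consortium_configs("adiponectin")
        assert sum(c.n_samples for c in configs) == 2791
        configs_l = simulate.default_consortium_configs("leptin")
        assert sum(c.n_samples for c in configs_l) == 3661

    def test_cohorts_share_truth_but_differ(self, small_consortium):
        datasets, truth = small_consortium
        assert len(datasets) == 5
        assert not np.allclose(datasets[0].beta.iloc[:10, :10],
                               datasets[1].beta.iloc[:10, :10])
        assert all(list(d.beta.columns) == list(truth.effects["cpg_id"])
                   for d in datasets)

    def test_determinism(self):
        configs = [CohortConfig(cohort_id=f"C{k}", n_samples=60, n_cpgs=40,
                                seed=11) for k in range(2)]
        a, _ = generate_consortium(configs)
        b, _ = generate_consortium(configs)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.beta, y.beta)

    def test_mismatched_cpg_sets_rejected(self):
        configs = [CohortConfig(n_samples=60, n_cpgs=40, seed=0),
                   CohortConfig(n_samples=60, n_cpgs=50, seed=0)]
        with pytest.raises(ValueError, match="CpG set"):
            generate_consortium(configs)


class TestAnnotation:
    def test_uniform_states_give_null_enrichment(self):
        from adipomethyl import enrich
        ann, genes, catalogue, bed = generate_annotation(400, 50, 5, seed=1)
        target = list(ann["cpg_id"][:40])
        res = enrich.run_state_enrichment(target, ann).set_index("feature")
        # no planted enrichment: no state should be significant
        assert not res["enriched"].any()

    def test_window_rule_excludes_distant_gene(self):
        from adipomethyl.eqtm import pair_cpgs_genes
        ann = pd.DataFrame({"cpg_id": ["cg1"], "chrom": ["chr1"], "pos": [50_000]})
        near = pd.DataFrame({"gene_id": ["G1"], "chrom": ["chr1"],
                             "start": [10_000], "end": [20_000]})
        far = pd.DataFrame({"gene_id": ["G2"], "chrom": ["chr1"],
                            "start": [200_000], "end": [210_000]})
        assert len(pair_cpgs_genes(ann, near)) == 1
        assert len(pair_cpgs_genes(ann, far)) == 0

    def test_segmentation_consistent_with_labels(self):
        from adipomethyl.io import state_at
        ann, _, _, bed = generate_annotation(100, 20, 3, seed=4)
        probe = ann.iloc[10]
        assert state_at(bed, probe["chrom"], probe["pos"]) == probe["state_E062"]


class TestGeneticScenario:
    def test_path_product_at_high_precision(self):
        # with huge study sizes the sampling noise vanishes and the GWAS
        # effect of a cis instrument equals beta_mQTL * gamma
        cfg = GeneticScenarioConfig(n_cpgs=20, n_mqtl=10**9, n_gwas=10**9)
        cis, gwas, _, _, truth = generate_genetic_scenario("forward", cfg, seed=2)
        g = truth.effects.set_index("cpg_id")["gamma"]
        merged = cis.merge(gwas, on="variant_id", suffixes=("_m", "_g"))
        expect = merged["beta_m"].to_numpy() * g.loc[merged["trait_id_m"]].to_numpy()
        assert np.allclose(merged["beta_g"], expect, atol=1e-3)

    def test_reverse_scenario_trans_effects(self):
        cfg = GeneticScenarioConfig(n_cpgs=10, n_mqtl=10**9, n_gwas=10**9)
        cis, gwas, trans, _, truth = generate_genetic_scenario("reverse", cfg, seed=3)
        lam = truth.effects.set_index("cpg_id")["lam"]
        inst = gwas[gwas["variant_id"].str.startswith("rs9")].set_index("variant_id")
        for _, row in trans.iterrows():
            expect = inst.loc[row["variant_id"], "beta"] * lam[row["trait_id"]]
            assert row["beta"] == pytest.approx(expect, abs=1e-3)
        # cis instruments have null adipokine effects in the reverse world
        cis_gwas = gwas[~gwas["variant_id"].str.startswith("rs9")]
        assert np.abs(cis_gwas["beta"]).max() < 1e-3

    def test_unknown_scenario_and_small_n_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            generate_genetic_scenario("sideways")
        with pytest.raises(ValueError, match="sample sizes"):
            GeneticScenarioConfig(n_mqtl=10)

    def test_se_scaling_with_eaf(self):
        cis, _, _, _, _ = generate_genetic_scenario(
            "null", GeneticScenarioConfig(n_cpgs=50), seed=5)
        implied = 1.0 / np.sqrt(GeneticScenarioConfig().n_mqtl * 2
                                * cis["eaf"] * (1 - cis["eaf"]))
        assert np.allclose(cis["se"], implied)


class TestExpression:
    def test_fixed_seed_identical(self):
        pairs = pd.DataFrame({"cpg_id": ["cg1"], "gene_id": ["GENE00000"]})
        a = generate_expression(50, 10, pairs, seed=8)
        b = generate_expression(50, 10, pairs, seed=8)
        pd.testing.assert_frame_equal(a[0], b[0])

    def test_null_effect_gives_uniform_p(self):
        from scipy import stats
        from adipomethyl import eqtm
        pairs = pd.DataFrame({"cpg_id": [f"cg{i}" for i in range(150)],
                              "gene_id": [f"GENE{i:05d}" for i in range(150)],
                              "effect": 0.0})
        counts, cov, meth, _ = generate_expression(300, 150, pairs, seed=6)
        expr, _ = eqtm.log2_cpm(counts)
        expr = expr.apply(lambda c: eqtm.rin(c), axis=0)
        res = eqtm.fit_eqtm(pairs, expr, meth, cov)
        assert stats.kstest(res["pval"], "uniform").pvalue > 0.01

    def test_majority_of_default_effects_negative(self):
        pairs = pd.DataFrame({"cpg_id": [f"cg{i}" for i in range(200)],
                              "gene_id": [f"GENE{i:05d}" for i in range(200)]})
        _, _, _, truth = generate_expression(10, 200, pairs, seed=7)
        assert (truth.effects["true_beta"] < 0).mean() > 0.5
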