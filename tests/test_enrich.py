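"""Catalogue filtering, 2x2/logistic enrichment and hypergeometric ORA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adipomethyl import enrich, simulate


def catalogue_row(trait="t", pubmed="123", n=1000, n_cpgs=200, has_pval=True,
                  age="adult", tissue="whole blood", cpgs="cg1,cg2"):
    return {"trait": trait, "pubmed_id": pubmed, "n": n,
            "n_cpgs_reported": n_cpgs, "has_pval": has_pval,
            "age_group": age, "tissue": tissue, "cpgs": cpgs}


class TestFilterCatalogue:
    def test_sample_size_boundary(self):
        df = pd.DataFrame([catalogue_row(trait="lo", n=499),
                           catalogue_row(trait="hi", n=500)])
        out = enrich.filter_catalogue(df)
        assert list(out["trait"]) == ["hi"]

    def test_each_criterion_drops(self):
        rows = [catalogue_row(trait="keep"),
                catalogue_row(trait="no_pmid", pubmed=""),
                catalogue_row(trait="few_cpgs", n_cpgs=99),
                catalogue_row(trait="no_p", has_pval=False),
                catalogue_row(trait="child", age="child"),
                catalogue_row(trait="saliva", tissue="saliva")]
        out = enrich.filter_catalogue(pd.DataFrame(rows))
        assert list(out["trait"]) == ["keep"]

    def test_synthetic_catalogue_counts(self):
        _, _, catalogue, _ = simulate.generate_annotation(200, 20, 100, seed=2)
        out = enrich.filter_catalogue(catalogue)
        keep = ((catalogue["pubmed_id"].astype(str).str.len() > 0)
                & (catalogue["n"] >= 500)
                & (catalogue["n_cpgs_reported"] >= 100)
                & catalogue["has_pval"]
                & (catalogue["age_group"] == "adult")
                & catalogue["tissue"].isin(["whole blood", "leukocytes"]))
        assert len(out) == int(keep.sum())

    def test_recode_merges_synonyms(self):
        df = pd.DataFrame([catalogue_row(trait="BMI", cpgs="cg1,cg2"),
                           catalogue_row(trait="body mass index", cpgs="cg2,cg3")])
        out = enrich.filter_catalogue(df, recode={"body mass index": "BMI"})
        assert list(out["trait"]) == ["BMI"]
        assert set(out["cpgs"].iloc[0].split(",")) == {"cg1", "cg2", "cg3"}

    def test_empty_recode_keeps_names(self):
        df = pd.DataFrame([catalogue_row(trait="HDL")])
        assert list(enrich.filter_catalogue(df)["trait"]) == ["HDL"]

    def test_missing_column_raises(self):
        with pytest.raises(ValueError, match="tissue"):
            enrich.filter_catalogue(pd.DataFrame([{"trait": "x"}]))


class TestTwoByTwo:
    @staticmethod
    def _sets(a, b, c, d):
        """Build target/feature/background with the given 2x2 counts."""
        background = [f"i{k}" for k in range(a + b + c + d)]
        target = background[: a + b]
        feature = background[:a] + background[a + b: a + b + c]
        return target, feature, background

    def test_cross_product_worked_example(self):
        # background 1000, target 100, feature 50, overlap 20 -> OR 7.25
        target, feature, background = self._sets(20, 80, 30, 870)
        res = enrich.two_by_two_enrichment(target, feature, background)
        assert (res.a, res.b, res.c, res.d) == (20, 80, 30, 870)
        assert res.odds_ratio == pytest.approx(7.25, rel=1e-6)

    def test_independence_gives_unit_or(self):
        target, feature, background = self._sets(10, 90, 90, 810)
        res = enrich.two_by_two_enrichment(target, feature, background)
        assert res.odds_ratio == pytest.approx(1.0, rel=1e-6)

    def test_logistic_equals_cross_product(self, rng):
        for _ in range(30):
            a, b, c, d = rng.integers(5, 200, size=4)
            target, feature, background = self._sets(a, b, c, d)
            res = enrich.two_by_two_enrichment(target, feature, background)
            assert res.odds_ratio == pytest.approx((a * d) / (b * c), rel=1e-6)
            assert not res.continuity_corrected

    def test_zero_overlap_continuity_corrected(self):
        target, feature, background = self._sets(0, 50, 100, 850)
        res = enrich.two_by_two_enrichment(target, feature, background)
        assert res.continuity_corrected
        assert 0 < res.odds_ratio < 1

    def test_role_symmetry(self, rng):
        a, b, c, d = 15, 40, 25, 300
        target, feature, background = self._sets(a, b, c, d)
        r1 = enrich.two_by_two_enrichment(target, feature, background)
        r2 = enrich.two_by_two_enrichment(feature, target, background)
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio, rel=1e-6)

    def test_target_outside_background_rejected(self):
        with pytest.raises(ValueError):
            enrich.two_by_two_enrichment(["x"], ["a"], ["a", "b"])


class TestStateEnrichment:
    def test_planted_enhancer_detected(self):
        ann, _, _, _ = simulate.generate_annotation(
            2000, 50, 3, seed=9, enriched_state="7_Enh",
            enriched_cpgs=[f"cg{j:08d}" for j in range(100)], enrichment_or=5.0)
        res = enrich.run_state_enrichment(
            [f"cg{j:08d}" for j in range(100)], ann).set_index("feature")
        assert res.loc["7_Enh", "qval"] <= 0.05
        assert res.loc["7_Enh", "odds_ratio"] > 2.0

    def test_absent_epigenome_rejected(self):
        ann, _, _, _ = simulate.generate_annotation(100, 10, 3, seed=1)
        with pytest.raises(ValueError, match="E999"):
            enrich.run_state_enrichment(["cg00000000"], ann, epigenome_id="E999")


class TestTraitEnrichment:
    def test_planted_trait_top_ranked(self):
        target = [f"cg{j:08d}" for j in range(100)]
        ann, _, catalogue, _ = simulate.generate_annotation(
            2000, 50, 20, seed=3, target_cpgs=target)
        filtered = enrich.filter_catalogue(catalogue)
        res = enrich.run_trait_enrichment(target, filtered, ann["cpg_id"])
        top = res.sort_values("odds_ratio", ascending=False).iloc[0]
        assert top["feature"] == "planted_trait"
        assert top["qval"] <= 0.05

    def test_trait_without_background_cpgs_skipped(self):
        catalogue = pd.DataFrame([catalogue_row(trait="ghost", cpgs="zz1,zz2")])
        res = enrich.run_trait_enrichment(["cg1"], catalogue,
                                          ["cg1", "cg2", "cg3"])
        assert res.empty


class TestOverrepresentation:
    def test_hypergeometric_matches_pmf_summation(self, rng):
        for _ in range(50):
            universe = [f"g{k}" for k in range(int(rng.integers(20, 200)))]
            set_size = int(rng.integers(1, len(universe)))
            list_size = int(rng.integers(1, len(universe)))
            members = list(rng.choice(universe, set_size, replace=False))
            query = list(rng.choice(universe, list_size, replace=False))
            res = enrich.overrepresentation(query, {"S": members}, universe)
            k = len(set(query) & set(members))
            pmf_sum = sum(stats.hypergeom.pmf(x, len(universe), set_size,
                                              list_size)
                          for x in range(k, min(set_size, list_size) + 1))
            assert res["pval"].iloc[0] == pytest.approx(pmf_sum, rel=1e-9,
                                                        abs=1e-12)

    def test_worked_example(self):
        universe = [f"g{k}" for k in range(100)]
        res = enrich.overrepresentation(
            universe[:8] + universe[50:52], {"S": universe[:20]}, universe)
        expect = float(stats.hypergeom.sf(7, 100, 20, 10))
        assert res["pval"].iloc[0] == pytest.approx(expect, rel=1e-12)

    def test_list_equal_to_set_is_extreme(self):
        universe = [f"g{k}" for k in range(50)]
        lib = {"S": universe[:10], "T": universe[10:30]}
        res = enrich.overrepresentation(universe[:10], lib).set_index("set_name")
        assert res.loc["S", "pval"] < res.loc["T", "pval"]
        assert res.loc["S", "pval"] < 1e-6

    def test_expected_overlap_not_significant(self):
        universe = [f"g{k}" for k in range(100)]
        # list of 10 vs set of 20: expected overlap 2
        query = universe[:2] + universe[50:58]
        res = enrich.overrepresentation(query, {"S": universe[:20]}, universe)
        assert res["pval"].iloc[0] > 0.3

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich.overrepresentation(["g1"], {}, [])
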