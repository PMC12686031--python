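"""Outlier rule, phenotype preprocessing and the per-CpG linear model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adipomethyl import ewas
from adipomethyl.simulate import CohortConfig, generate_cohort


def normal_equations_oracle(y, X):
    """Independent OLS oracle via explicit normal equations."""
    xtx = X.T @ X
    coef = np.linalg.inv(xtx) @ X.T @ y
    resid = y - X @ coef
    df = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * np.linalg.inv(xtx)[1, 1])
    t = coef[1] / se
    p = 2 * stats.t.sf(abs(t), df)
    return coef[1], se, p


class TestFlagOutliers:
    def test_three_iqr_rule_worked_example(self):
        # Q1=2, Q3=4 under linear interpolation; bounds [-4, 10]; 100 flagged
        flags = ewas.flag_outliers([1, 2, 3, 4, 100])
        assert flags["outlier"].tolist() == [False] * 4 + [True]

    def test_all_equal_vector_flags_nothing(self):
        flags = ewas.flag_outliers([5.0] * 10)
        assert not flags["outlier"].any()

    def test_too_few_values_error(self):
        with pytest.raises(ValueError, match=">= 4"):
            ewas.flag_outliers([1, 2, 3])

    def test_missing_values_flagged_separately(self):
        flags = ewas.flag_outliers([1, 2, np.nan, 3, 4])
        assert flags["missing"].tolist() == [False, False, True, False, False]
        assert not flags["outlier"].any()

    def test_gaussian_tail_mass_tiny(self, rng):
        # 3-IQR bound on a standard normal sits at ~4.72 SD: well under 0.1%
        v = rng.standard_normal(10_000)
        assert ewas.flag_outliers(v)["outlier"].mean() < 0.001


class TestPreprocessAdipokine:
    def test_lod_then_log(self):
        logged, report = ewas.preprocess_adipokine([0.1, 5, 7, 6, 5.5], lod=1.0)
        assert report["below_lod"] == 1
        assert np.isnan(logged.iloc[0])
        assert logged.iloc[1] == pytest.approx(np.log(5))

    def test_clean_vector_identity_up_to_log(self):
        vals = [2.0, 3.0, 4.0, 5.0]
        logged, report = ewas.preprocess_adipokine(vals)
        assert report["below_lod"] == 0 and report["outlier"] == 0
        assert np.allclose(logged, np.log(vals))

    def test_planted_censoring_count_recovered(self, rng):
        raw = np.exp(rng.normal(2.0, 0.5, size=1000))
        lod = np.quantile(raw, 0.01)
        _, report = ewas.preprocess_adipokine(raw, lod=lod)
        assert report["below_lod"] == int((raw < lod).sum())

    def test_all_removed_raises(self):
        with pytest.raises(ValueError, match="all adipokine values"):
            ewas.preprocess_adipokine([0.1, 0.2, 0.3, 0.2], lod=10.0)


class TestFitProbe:
    def test_noiseless_exact(self):
        x = np.linspace(0, 1, 30)
        rec = ewas.fit_probe(0.1 + 0.02 * x, x)
        assert rec["beta"] == pytest.approx(0.02, abs=1e-12)
        assert rec["n"] == 30

    def test_effect_only_via_included_covariate(self, rng):
        z = rng.standard_normal(200)
        x = rng.standard_normal(200)  # orthogonal to z in expectation
        x = x - z * (x @ z) / (z @ z)  # exactly orthogonalized
        y = 0.3 * z + 1e-12 * rng.standard_normal(200)
        rec = ewas.fit_probe(y, x, covariates=z)
        assert abs(rec["beta"]) < 1e-9

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(50):
            n = 200
            X = np.column_stack([np.ones(n), rng.standard_normal((n, 4))])
            y = X @ rng.normal(0, 1, size=5) + rng.standard_normal(n)
            rec = ewas.fit_probe(y, X[:, 1], X[:, 2:])
            b, s, p = normal_equations_oracle(y, X)
            assert rec["beta"] == pytest.approx(b, rel=1e-10)
            assert rec["se"] == pytest.approx(s, rel=1e-10)
            assert rec["pval"] == pytest.approx(p, rel=1e-8, abs=1e-15)

    def test_rank_deficient_design_raises(self):
        x = np.arange(20.0)
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            ewas.fit_probe(x * 0.1, x, covariates=np.column_stack([x, x]))


class TestRunModel:
    def test_deterministic(self):
        ds, _ = generate_cohort(CohortConfig(n_samples=120, n_cpgs=60, seed=4))
        a = ewas.run_model(ds, ewas.ModelSpec())
        b = ewas.run_model(ds, ewas.ModelSpec())
        pd.testing.assert_frame_equal(a, b)

    def test_planted_cpgs_rank_top(self):
        cfg = CohortConfig(n_samples=600, n_cpgs=300, frac_causal=0.03,
                           effect_size_sd=0.05, seed=6)
        ds, truth = generate_cohort(cfg)
        rec = ewas.run_model(ds, ewas.ModelSpec())
        rec["absz"] = (rec["beta"] / rec["se"]).abs()
        top = set(rec.nlargest(9, "absz")["cpg_id"])
        assert len(top & set(truth.causal_ids())) >= 8

    def test_sensitivity_models_drop_missing_covariates(self):
        ds, _ = generate_cohort(CohortConfig(n_samples=300, n_cpgs=20, seed=8))
        base = ewas.run_model(ds, ewas.ModelSpec(model_tag="base"))
        smoke = ewas.run_model(ds, ewas.ModelSpec(model_tag="smoking"))
        bmi = ewas.run_model(ds, ewas.ModelSpec(model_tag="bmi"))
        logged, _ = ewas.preprocess_adipokine(
            ds.covariates["adipokine_raw"].to_numpy())
        pheno_kept = logged.notna().to_numpy()
        assert base["n"].iloc[0] == int(pheno_kept.sum())
        expected_smoke = int((pheno_kept
                              & ds.covariates["smoking"].notna().to_numpy()).sum())
        assert smoke["n"].iloc[0] == expected_smoke
        assert bmi["n"].iloc[0] < base["n"].iloc[0]

    def test_extended_cells_exclude_neutrophils(self):
        spec = ewas.ModelSpec(model_tag="extended_cells")
        assert "Neu" not in spec.covariate_columns()
        assert len([c for c in spec.covariate_columns()
                    if c in __import__("adipomethyl").simulate.EXTENDED_CELLS]) == 11

    def test_null_pvalues_uniform(self):
        ds, _ = generate_cohort(CohortConfig(n_samples=400, n_cpgs=800,
                                             frac_causal=0.0, seed=10))
        rec = ewas.run_model(ds, ewas.ModelSpec())
        assert stats.kstest(rec["pval"], "uniform").pvalue > 0.01


class TestFilterProbes:
    @staticmethod
    def _annotation(cpgs, **flags):
        ann = pd.DataFrame({"cpg_id": cpgs,
                            "chrom": "chr1", "pos": range(1, len(cpgs) + 1),
                            "on_sex_chrom": False, "blacklisted": False,
                            "variant_or_ambiguous": False})
        for col, ids in flags.items():
            ann.loc[ann["cpg_id"].isin(ids), col] = True
        return ann

    def test_low_n_boundary(self):
        rec = pd.DataFrame({"cpg_id": ["a", "b"], "beta": 0.1, "se": 0.1,
                            "pval": 0.5, "n": [49, 50]})
        ann = self._annotation(["a", "b"])
        out, report = ewas.filter_probes(rec, ann)
        assert list(out["cpg_id"]) == ["b"]
        assert report.dropped["low_n"] == 1

    def test_flagged_probes_dropped_exactly(self):
        cpgs = [f"c{i}" for i in range(20)]
        rec = pd.DataFrame({"cpg_id": cpgs, "beta": 0.1, "se": 0.1,
                            "pval": 0.5, "n": 100})
        ann = self._annotation(cpgs, on_sex_chrom=["c0", "c1"],
                               blacklisted=["c2", "c3", "c4"],
                               variant_or_ambiguous=["c5", "c6"])
        out, report = ewas.filter_probes(rec, ann)
        assert len(out) == 13
        assert sum(report.dropped.values()) == 7

    def test_clean_input_is_identity(self):
        cpgs = [f"c{i}" for i in range(5)]
        rec = pd.DataFrame({"cpg_id": cpgs, "beta": 0.1, "se": 0.1,
                            "pval": 0.5, "n": 100})
        out, _ = ewas.filter_probes(rec, self._annotation(cpgs))
        pd.testing.assert_frame_equal(out, rec)

    def test_unannotated_cpg_listed(self):
        rec = pd.DataFrame({"cpg_id": ["a", "zz"], "beta": 0.1, "se": 0.1,
                            "pval": 0.5, "n": 100})
        with pytest.raises(ValueError, match="zz"):
            ewas.filter_probes(rec, self._annotation(["a"]))
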