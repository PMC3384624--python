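"""Transform contract, OLS association, multiple testing, strata, SNPs."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

from ffmnet import associate
from ffmnet.associate import ModelSpec, TransformSpec


class TestTransform:
    def test_lognormal_sample_standardised(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(3, 0.5, 500)
        z = associate.transform(x)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12

    def test_matches_ln_then_zscore_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(2, 0.4, 200)
        z = associate.transform(x)
        lx = np.log(x)
        oracle = (lx - lx.mean()) / lx.std(ddof=1)
        np.testing.assert_allclose(z, oracle, atol=1e-12)

    def test_monotone(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(1, 0.6, 100)
        z = associate.transform(x)
        order = np.argsort(x)
        assert (np.diff(z[order]) > 0).all()

    def test_rank_inverse_normal_standardised_and_monotone(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(1, 1.2, 301)
        z = associate.transform(x, TransformSpec(kind="rank_inverse_normal"))
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12
        order = np.argsort(x)
        assert (np.diff(z[order]) >= 0).all()

    def test_zeros_replaced_by_epsilon_rule(self):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        z = associate.transform(x, TransformSpec(epsilon=0.5))
        oracle = np.log(np.array([0.5, 1.0, 2.0, 4.0]))
        oracle = (oracle - oracle.mean()) / oracle.std(ddof=1)
        np.testing.assert_allclose(z, oracle, atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            associate.transform(np.full(10, 7.0))

    @given(scale=st.floats(1e-3, 1e3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(4)
        x = rng.lognormal(2, 0.5, 50)
        np.testing.assert_allclose(
            associate.transform(x), associate.transform(scale * x),
            atol=1e-10)


class TestFitLinear:
    def test_exact_line(self):
        x = np.arange(1.0, 21.0)
        data = pd.DataFrame({"y": 2 * x, "ffmi": x})
        res = associate.fit_linear(
            ModelSpec(covariates=(), response="y"), data)
        assert res.beta == pytest.approx(2.0, abs=1e-10)
        assert res.r2_adj == pytest.approx(1.0, abs=1e-10)
        assert res.p < 1e-30
        assert res.direction == "pos"

    def test_matches_statsmodels(self, toy_pheno):
        rng = np.random.default_rng(5)
        pheno = toy_pheno.copy()
        pheno["ffmi"] = pheno["ffm_kg"] / pheno["height_m"] ** 2
        pheno["y"] = (0.1 * pheno["ffmi"] + 0.05 * pheno["age"]
                      + rng.normal(0, 1, len(pheno)))
        res = associate.fit_linear(
            ModelSpec(covariates=("age", "sex"), response="y"), pheno)
        X = sm.add_constant(pheno[["ffmi", "age", "sex"]].astype(float))
        ref = sm.OLS(pheno["y"], X).fit()
        assert res.beta == pytest.approx(ref.params["ffmi"], rel=1e-10)
        assert res.se == pytest.approx(ref.bse["ffmi"], rel=1e-10)
        assert res.p == pytest.approx(ref.pvalues["ffmi"], rel=1e-8)
        assert res.r2_adj == pytest.approx(ref.rsquared_adj, rel=1e-10)

    def test_batch_enters_as_indicators(self, toy_pheno):
        rng = np.random.default_rng(6)
        pheno = toy_pheno.copy()
        pheno["ffmi"] = pheno["ffm_kg"] / pheno["height_m"] ** 2
        shift = pheno["batch"].map({0: 0.0, 1: 0.8, 2: -0.5})
        pheno["y"] = shift + rng.normal(0, 0.5, len(pheno))
        res = associate.fit_linear(
            ModelSpec(covariates=("age", "sex", "batch"), response="y"),
            pheno)
        dummies = pd.get_dummies(pheno["batch"], drop_first=True, dtype=float)
        X = sm.add_constant(pd.concat(
            [pheno[["ffmi", "age", "sex"]].astype(float), dummies], axis=1))
        ref = sm.OLS(pheno["y"], X).fit()
        assert res.beta == pytest.approx(ref.params["ffmi"], rel=1e-10)
        assert res.r2_adj == pytest.approx(ref.rsquared_adj, rel=1e-10)

    def test_collinear_design_rejected(self, toy_pheno):
        pheno = toy_pheno.copy()
        pheno["ffmi"] = 3.0
        pheno["y"] = 1.0 * pheno["age"]
        with pytest.raises(ValueError, match="collinear"):
            associate.fit_linear(
                ModelSpec(covariates=("age",), response="y"), pheno)

    def test_null_p_values_uniform(self):
        # 500 independent null responses, one shared design: the p-value
        # sample must be consistent with U(0,1)
        rng = np.random.default_rng(7)
        n = 1000
        pheno = pd.DataFrame({
            "ffmi": rng.normal(18, 2, n),
            "age": rng.uniform(51, 80, n),
            "sex": rng.integers(0, 2, n),
        })
        Y = rng.standard_normal((n, 500))
        X, _ = associate._design(pheno, ModelSpec())
        _, _, p, _ = associate._ols_multi(X, Y)
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_coverage_of_two_se_interval(self):
        # planted standardized beta 0.14 at n=965: the 2-SE interval
        # covers the truth in about 95% of replicates
        rng = np.random.default_rng(8)
        n, reps, beta_true = 965, 200, 0.14
        hits = 0
        for _ in range(reps):
            ffmi = rng.normal(18.4, 2.2, n)
            age = rng.uniform(51, 80, n)
            sex = rng.integers(0, 2, n)
            sd_noise = np.sqrt(1 - beta_true**2 * 2.2**2)
            y = beta_true * ffmi + rng.normal(0, sd_noise, n)
            pheno = pd.DataFrame({"ffmi": ffmi, "age": age, "sex": sex})
            X, _ = associate._design(pheno, ModelSpec())
            b, se, _, _ = associate._ols_multi(X, y)
            hits += abs(b[0] - beta_true) <= 2 * se[0]
        assert hits / reps >= 0.90


class TestMultipleTesting:
    def test_uncorrelated_panel_close_to_bonferroni(self):
        rng = np.random.default_rng(9)
        Z = pd.DataFrame(rng.standard_normal((4000, 166)))
        thr = associate.multiple_testing_threshold(Z, method="effective")
        assert thr == pytest.approx(0.05 / 166, rel=0.07)

    def test_perfectly_correlated_panel_collapses_to_alpha(self):
        rng = np.random.default_rng(10)
        base = rng.standard_normal(200)
        Z = pd.DataFrame({f"m{i}": base * (i + 1) for i in range(8)})
        thr = associate.multiple_testing_threshold(Z, method="effective")
        assert thr == pytest.approx(0.05, rel=1e-6)

    def test_fixed_replay(self):
        Z = pd.DataFrame(np.random.default_rng(0).standard_normal((10, 3)))
        thr = associate.multiple_testing_threshold(
            Z, method="fixed", fixed=3.12e-4)
        assert thr == 3.12e-4

    def test_bonferroni(self):
        Z = pd.DataFrame(np.random.default_rng(0).standard_normal((10, 4)))
        assert associate.multiple_testing_threshold(
            Z, method="bonferroni") == 0.05 / 4


class TestMwas:
    @pytest.fixture()
    def planted(self):
        rng = np.random.default_rng(11)
        n = 600
        pheno = pd.DataFrame({
            "ffmi": rng.normal(18.4, 2.2, n),
            "age": rng.uniform(51, 80, n),
            "sex": rng.integers(0, 2, n),
        }, index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"))
        z_signal = 0.15 * (pheno["ffmi"] - pheno["ffmi"].mean()) \
            + rng.normal(0, 0.8, n)
        z_null = rng.normal(0, 1, n)
        vals = pd.DataFrame({
            "hit": np.exp(3 + 0.3 * z_signal),
            "null": np.exp(2 + 0.5 * z_null),
        }, index=pheno.index)
        return vals, pheno

    def test_planted_effect_flagged_null_not(self, planted):
        vals, pheno = planted
        res = associate.mwas(vals, pheno).set_index("trait")
        assert bool(res.loc["hit", "significant"])
        assert not bool(res.loc["null", "significant"])

    def test_column_order_irrelevant(self, planted):
        vals, pheno = planted
        a = associate.mwas(vals, pheno).set_index("trait")
        b = associate.mwas(vals[["null", "hit"]], pheno).set_index("trait")
        for t in ("hit", "null"):
            assert a.loc[t, "p"] == pytest.approx(b.loc[t, "p"], rel=1e-12)

    def test_empty_panel_gives_empty_results(self, planted):
        _, pheno = planted
        with pytest.raises(ValueError, match="no tests"):
            associate.mwas(pd.DataFrame(index=pheno.index), pheno)

    def test_scale_invariant_inference(self, planted):
        vals, pheno = planted
        a = associate.mwas(vals, pheno)
        b = associate.mwas(vals * 1000.0, pheno)
        np.testing.assert_allclose(a["p"], b["p"], rtol=1e-10)
        np.testing.assert_allclose(a["beta"], b["beta"], rtol=1e-10)

    def test_adjustment_removes_confounding(self):
        # age drives both FFMI and the metabolite: adjusted model is
        # calibrated, unadjusted model is confounded
        rng = np.random.default_rng(12)
        n, reps = 400, 120
        p_adj, p_raw = [], []
        for _ in range(reps):
            age = rng.uniform(51, 80, n)
            ffmi = 10 + 0.15 * age + rng.normal(0, 1.5, n)
            z = 0.04 * (age - age.mean()) + rng.normal(0, 1, n)
            vals = pd.DataFrame({"m": np.exp(2 + 0.3 * z)})
            pheno = pd.DataFrame({"ffmi": ffmi, "age": age,
                                  "sex": rng.integers(0, 2, n)})
            a = associate.mwas(vals, pheno, ModelSpec(covariates=("age",)))
            r = associate.mwas(vals, pheno, ModelSpec(covariates=()))
            p_adj.append(float(a["p"].iloc[0]))
            p_raw.append(float(r["p"].iloc[0]))
        rate_adj = np.mean(np.array(p_adj) < 0.05)
        rate_raw = np.mean(np.array(p_raw) < 0.05)
        assert rate_adj < 0.15
        assert rate_raw > 0.3


class TestStratified:
    @pytest.fixture()
    def cohort(self):
        rng = np.random.default_rng(13)
        n = 800
        pheno = pd.DataFrame({
            "ffmi": rng.normal(18.4, 2.2, n),
            "age": rng.uniform(51, 80, n),
            "sex": rng.integers(0, 2, n),
            "bmi": rng.normal(28, 4, n),
            "activity": np.where(rng.random(n) < 0.45, "active", "inactive"),
        }, index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"))
        nonobese = (pheno["bmi"] < 30).to_numpy()
        z = np.where(nonobese, 0.16, 0.0) * \
            (pheno["ffmi"] - pheno["ffmi"].mean())
        vals = pd.DataFrame(
            {"m": np.exp(3 + 0.3 * (z + rng.normal(0, 0.9, n)))},
            index=pheno.index)
        return vals, pheno

    def test_bmi_strata_reproduce_planted_contrast(self, cohort):
        vals, pheno = cohort
        res = associate.stratified_mwas(vals, pheno, strata=("bmi",),
                                        threshold_method="bonferroni")
        non = res["non_obese"].set_index("trait")
        ob = res["obese"].set_index("trait")
        assert bool(non.loc["m", "significant"])
        assert not bool(ob.loc["m", "significant"])

    def test_sex_strata_sizes_sum_to_total(self, cohort):
        vals, pheno = cohort
        res = associate.stratified_mwas(vals, pheno, strata=("sex",))
        assert res["male"]["n"].iloc[0] + res["female"]["n"].iloc[0] \
            == len(pheno)

    def test_degenerate_partition_equals_mwas(self, cohort):
        vals, pheno = cohort
        whole = associate.mwas(vals, pheno)
        strat = associate.stratified_mwas(
            vals, pheno.assign(bmi=20.0), strata=("bmi",))
        assert list(strat) == ["non_obese"]
        assert strat["non_obese"]["p"].iloc[0] == pytest.approx(
            whole["p"].iloc[0], rel=1e-12)

    def test_small_stratum_skipped(self, cohort):
        vals, pheno = cohort
        pheno = pheno.copy()
        pheno.loc[pheno.index[1:], "bmi"] = 20.0   # one obese subject
        res = associate.stratified_mwas(vals, pheno, strata=("bmi",))
        assert "obese" not in res


class TestSnpAssociation:
    @pytest.fixture()
    def genetic(self):
        rng = np.random.default_rng(14)
        n = 668
        pheno = pd.DataFrame({
            "age": rng.uniform(51, 80, n),
            "sex": rng.integers(0, 2, n),
            "ffmi": rng.normal(18, 2, n),
        }, index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"))
        dosages = pd.DataFrame({
            "snp_effect": rng.binomial(2, 0.3, n).astype(float),
            "snp_null": rng.binomial(2, 0.2, n).astype(float),
            "snp_mono": np.zeros(n),
        }, index=pheno.index)
        z = 0.5 * (dosages["snp_effect"] - dosages["snp_effect"].mean()) \
            + rng.normal(0, 1, n)
        vals = pd.DataFrame({"m": np.exp(2 + 0.4 * z)}, index=pheno.index)
        return dosages, vals, pheno

    def test_planted_additive_effect_detected(self, genetic):
        dosages, vals, pheno = genetic
        res = associate.snp_association(dosages, vals, pheno,
                                        fixed_threshold=4.73e-6)
        res = res.set_index("snp")
        assert bool(res.loc["snp_effect", "significant"])
        assert not bool(res.loc["snp_null", "significant"])

    def test_monomorphic_skipped(self, genetic):
        dosages, vals, pheno = genetic
        res = associate.snp_association(dosages, vals, pheno)
        assert "snp_mono" not in set(res["snp"])

    def test_dosage_range_enforced(self, genetic):
        dosages, vals, pheno = genetic
        bad = dosages.copy()
        bad.iloc[0, 0] = 2.5
        with pytest.raises(ValueError, match="dosages"):
            associate.snp_association(bad, vals, pheno)

    def test_null_family_wise_error_controlled(self):
        # 20 null SNPs x 5 metabolites over repeated cohorts: the fixed
        # threshold keeps family-wise error far below alpha
        rng = np.random.default_rng(15)
        n = 300
        false_hits = 0
        for _ in range(30):
            pheno = pd.DataFrame({
                "age": rng.uniform(51, 80, n),
                "sex": rng.integers(0, 2, n),
            }, index=range(n))
            dosages = pd.DataFrame(
                rng.binomial(2, 0.3, (n, 20)).astype(float),
                index=pheno.index,
                columns=[f"snp{i}" for i in range(20)])
            vals = pd.DataFrame(
                np.exp(rng.normal(2, 0.4, (n, 5))), index=pheno.index,
                columns=[f"m{i}" for i in range(5)])
            res = associate.snp_association(dosages, vals, pheno,
                                            fixed_threshold=4.73e-6)
            false_hits += int(res["significant"].sum() > 0)
        assert false_hits <= 2
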