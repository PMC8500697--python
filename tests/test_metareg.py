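import math
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_coeffs
from mhshock import metareg


class TestDeltaLogit:
    def test_identity_when_unchanged(self):
        d, _ = metareg.delta_logit(0.05, 0.05, 800, 900)
        assert d == 0.0

    def test_closed_form_value(self):
        # independent hand computation: ln(0.08/0.92) - ln(0.05/0.95)
        expected = math.log(0.08 / 0.92) - math.log(0.05 / 0.95)
        d, _ = metareg.delta_logit(0.05, 0.08, 1000, 1000)
        assert d == pytest.approx(expected, abs=1e-12)
        assert d == pytest.approx(0.5021, abs=5e-4)

    def test_delta_method_se(self):
        _, se = metareg.delta_logit(0.5, 0.5, 100, 100)
        assert se == pytest.approx(math.sqrt(1 / 25 + 1 / 25), abs=1e-12)
        assert se == pytest.approx(0.2828, abs=5e-4)

    @pytest.mark.parametrize("pre,mid", [(0.0, 0.05), (0.05, 1.0), (1.0, 0.0)])
    def test_boundary_rejected_without_continuity(self, pre, mid):
        with pytest.raises(ValueError, match="boundary"):
            metareg.delta_logit(pre, mid, 100, 100)

    def test_continuity_correction(self):
        d, se = metareg.delta_logit(0.0, 0.05, 100, 200, continuity=True)
        # pre becomes 0.5/101
        assert np.isfinite(d) and se > 0
        expected_pre = 0.5 / 101
        assert d == pytest.approx(
            math.log(0.05 / 0.95) - math.log(expected_pre / (1 - expected_pre)))


def _wls_frame(seed, n=30):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "delta_logit": rng.normal(0.2, 0.3, n),
        "se_delta": rng.uniform(0.05, 0.3, n),
        "mobility_decrease": rng.uniform(0.05, 0.6, n),
        "sqrt_infection": rng.uniform(0.0, 0.03, n),
        "sqrt_excess": rng.uniform(0.0, 0.004, n),
        "cs_quota": (rng.random(n) < 0.3).astype(float),
        "sample_id": [f"s{i}" for i in range(n)],
    })


class TestIndicatorModel:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_wls_oracle_equivalence(self, seed):
        """With random-effect variances pinned to 0 the fixed effects must
        equal closed-form weighted least squares."""
        frame = _wls_frame(seed)
        fit = metareg.fit_indicator_model(frame, excess_direction="none",
                                          fix_tau={0: 0.0, 1: 0.0},
                                          n_draws=10, seed=0)
        X = frame[["mobility_decrease", "sqrt_infection", "sqrt_excess",
                   "cs_quota"]].to_numpy()
        w = 1.0 / frame["se_delta"].to_numpy() ** 2
        beta_wls = np.linalg.solve((X.T * w) @ X,
                                   (X.T * w) @ frame["delta_logit"].to_numpy())
        np.testing.assert_allclose(fit.beta, beta_wls, atol=1e-8)

    @pytest.mark.parametrize("method,rmeth", [("ml", "ML"), ("reml", "REML")])
    def test_matches_metafor_random_intercept(self, method, rmeth):
        """Independent oracle: R metafor's mixed-effects meta-regression with
        known sampling variances (one observation per sample makes the
        per-sample random intercept the classic between-study heterogeneity),
        in both maximum-likelihood and restricted-ML modes."""
        rng = np.random.default_rng(12)
        n = 40
        frame = pd.DataFrame({
            "mobility_decrease": rng.uniform(0.1, 0.6, n),
            "sqrt_infection": rng.uniform(0.0, 0.03, n),
            "sqrt_excess": np.full(n, 0.001),
            "se_delta": rng.uniform(0.05, 0.25, n),
            "cs_quota": 0.0,
            "sample_id": [f"s{i}" for i in range(n)],
        })
        frame["delta_logit"] = (0.8 * frame["mobility_decrease"]
                                + 12.0 * frame["sqrt_infection"]
                                + rng.normal(0, 0.15, n)
                                + rng.normal(0, frame["se_delta"]))
        fit = metareg.fit_indicator_model(frame, excess_direction="none",
                                          fix_tau={1: 0.0}, n_draws=10, seed=0,
                                          method=method)
        with tempfile.TemporaryDirectory() as td:
            frame.assign(vi=frame["se_delta"] ** 2).to_csv(f"{td}/d.csv",
                                                           index=False)
            rcode = (
                'suppressMessages(library(metafor));'
                f'd <- read.csv("{td}/d.csv");'
                'f <- rma(yi=delta_logit, vi=vi, mods=~mobility_decrease'
                f'+sqrt_infection+sqrt_excess-1, data=d, method="{rmeth}");'
                'cat(coef(f), f$tau2, sep=",")')
            out = subprocess.run(["Rscript", "-e", rcode],
                                 capture_output=True, text=True, check=True)
        ref = np.array([float(v) for v in out.stdout.strip().split(",")])
        np.testing.assert_allclose(fit.beta[:3], ref[:3], rtol=2e-4)
        assert fit.re_var_intercept == pytest.approx(ref[3], rel=2e-3)

    def test_null_outcome_gives_null_coefficients(self):
        frame = _wls_frame(5)
        frame["delta_logit"] = 0.0
        fit = metareg.fit_indicator_model(frame, excess_direction="none",
                                          n_draws=10, seed=0)
        np.testing.assert_allclose(fit.beta, 0.0, atol=1e-6)

    def test_degenerate_column_named(self):
        frame = _wls_frame(6)
        frame["sqrt_excess"] = 0.0
        with pytest.raises(ValueError, match="sqrt_excess"):
            metareg.fit_indicator_model(frame, n_draws=10, seed=0)

    def test_directional_prior_respected_in_every_draw(self):
        """Simulated negative excess effect: the nonnegativity prior pins the
        estimate at the boundary and every posterior draw respects the sign."""
        rng = np.random.default_rng(3)
        frame = _wls_frame(3, n=60)
        frame["delta_logit"] = (-80.0 * frame["sqrt_excess"]
                                + rng.normal(0, 0.05, 60))
        fit = metareg.fit_indicator_model(frame, excess_direction="nonnegative",
                                          n_draws=500, seed=4)
        assert fit.beta[fit._idx("sqrt_excess")] == 0.0
        assert np.all(fit.draws_for("sqrt_excess") >= 0.0)

    def test_needs_two_samples(self):
        frame = _wls_frame(7)
        frame["sample_id"] = "only_one"
        with pytest.raises(ValueError, match="sample"):
            metareg.fit_indicator_model(frame, n_draws=10, seed=0)

    def test_trimming_drops_worst_observations(self):
        frame = _wls_frame(8, n=40)
        frame.loc[0, "delta_logit"] = 25.0  # gross outlier
        fit_all = metareg.fit_indicator_model(frame, excess_direction="none",
                                              n_draws=10, seed=0)
        fit_trim = metareg.fit_indicator_model(frame, excess_direction="none",
                                               trim=0.05, n_draws=10, seed=0)
        assert fit_trim.n_obs == 38  # ceil(0.05*40)=2 observations removed
        # the outlier's leverage must be gone from the trimmed fit
        assert np.abs(fit_trim.beta).max() < np.abs(fit_all.beta).max()


class TestImpactIndex:
    def test_zero_exposure_zero_index_every_draw(self):
        coeffs = make_coeffs(
            {"mobility_decrease": 0.9, "sqrt_infection": 18.1, "sqrt_excess": 5.0},
            roles={n: "indicator" for n in metareg.INDICATOR_NAMES})
        idx = metareg.compute_impact_index(
            {"mobility_decrease": 0.0, "sqrt_infection": 0.0, "sqrt_excess": 0.0},
            coeffs)
        assert idx.shape == (1000,)
        assert np.all(idx == 0.0)

    def test_hand_evaluated_linear_combination(self):
        coeffs = make_coeffs(
            {"mobility_decrease": 0.9, "sqrt_infection": 18.1, "sqrt_excess": 5.0},
            roles={n: "indicator" for n in metareg.INDICATOR_NAMES},
            pvalues={"mobility_decrease": 0.001, "sqrt_infection": 0.001,
                     "sqrt_excess": 0.5})
        idx = metareg.compute_impact_index(
            {"mobility_decrease": 0.2, "sqrt_infection": np.sqrt(1e-4),
             "sqrt_excess": 0.1}, coeffs, per_draw=False)
        assert idx == pytest.approx(0.9 * 0.2 + 18.1 * 0.01, abs=1e-12)
        assert idx == pytest.approx(0.361, abs=1e-6)

    def test_insignificant_excess_never_enters_index(self):
        coeffs = make_coeffs(
            {"mobility_decrease": 0.9, "sqrt_infection": 18.1, "sqrt_excess": 50.0},
            roles={n: "indicator" for n in metareg.INDICATOR_NAMES},
            pvalues={"sqrt_excess": 0.6})
        a = metareg.compute_impact_index(
            {"mobility_decrease": 0.2, "sqrt_infection": 0.01,
             "sqrt_excess": 0.0}, coeffs)
        b = metareg.compute_impact_index(
            {"mobility_decrease": 0.2, "sqrt_infection": 0.01,
             "sqrt_excess": 0.004}, coeffs)
        np.testing.assert_array_equal(a, b)


FINAL_ROLES = {"index": "index", "mean_age": "modifier",
               "prop_female": "modifier", "cs_quota": "additive_bias"}


class TestPredictShift:
    def test_hand_evaluated_shift(self):
        coeffs = make_coeffs({"index": 0.4, "mean_age": -0.007,
                              "prop_female": 0.1}, roles=FINAL_ROLES)
        s = metareg.predict_logit_shift(1.0, coeffs, mean_age=30.0,
                                        prop_female=0.5, per_draw=False)
        assert s == pytest.approx((0.4 - 0.007 * 30 + 0.1 * 0.5) * 1.0, abs=1e-12)
        assert s == pytest.approx(0.24, abs=1e-12)

    def test_additive_quota_bias_survives_zero_impact(self):
        coeffs = make_coeffs({"index": 0.4, "cs_quota": 0.6}, roles=FINAL_ROLES)
        s = metareg.predict_logit_shift(0.0, coeffs, cs_quota=1.0,
                                        per_draw=False)
        assert s == pytest.approx(0.6, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(b_index=st.floats(-2, 2), b_age=st.floats(-0.05, 0.05),
           b_sex=st.floats(-1, 1), age=st.floats(15, 90),
           pf=st.floats(0, 1))
    def test_zero_impact_neutrality(self, b_index, b_age, b_sex, age, pf):
        """For any coefficients and covariates, zero impact with reference
        bias flags predicts exactly zero change."""
        coeffs = make_coeffs({"index": b_index, "mean_age": b_age,
                              "prop_female": b_sex}, roles=FINAL_ROLES,
                             n_draws=50)
        s = metareg.predict_logit_shift(0.0, coeffs, mean_age=age,
                                        prop_female=pf)
        assert np.all(s == 0.0)

    def test_monotone_in_index_with_positive_draws(self):
        coeffs = make_coeffs({"index": 0.5, "mean_age": -0.002},
                             roles=FINAL_ROLES)
        lo = metareg.predict_logit_shift(0.3, coeffs, mean_age=40.0)
        hi = metareg.predict_logit_shift(0.6, coeffs, mean_age=40.0)
        assert np.all(hi > lo)


class TestFinalModel:
    @staticmethod
    def _frame(seed, n=80, noise_col=True):
        rng = np.random.default_rng(seed)
        f = pd.DataFrame({
            "mean_age": rng.uniform(25, 60, n),
            "prop_female": rng.uniform(0.4, 0.6, n),
            "combined_symptoms": (rng.random(n) < 0.5).astype(float),
            "cs_random": 0.0, "long_quota": 0.0,
            "cs_quota": (rng.random(n) < 0.4).astype(float),
            "se_delta": rng.uniform(0.05, 0.15, n),
            "sample_id": [f"s{i}" for i in range(n)],
        })
        index = rng.uniform(0.2, 1.2, n)
        f["_index"] = index
        f["delta_logit"] = ((1.0 - 0.01 * f["mean_age"]) * index
                            + 0.9 * f["cs_quota"]
                            + rng.normal(0, f["se_delta"]))
        return f

    def test_pure_noise_covariate_eliminated(self):
        """combined_symptoms is independent of the outcome by construction
        and must be removed by backward elimination."""
        f = self._frame(21)
        fit = metareg.fit_final_model(
            f, f["_index"], candidates=["mean_age", "combined_symptoms",
                                        "cs_quota"], n_draws=50, seed=1)
        assert "combined_symptoms" not in fit.names
        assert any(e["dropped"] == "combined_symptoms"
                   for e in fit.elimination_log)

    def test_informative_covariates_retained(self):
        f = self._frame(22, n=150)
        fit = metareg.fit_final_model(f, f["_index"],
                                      candidates=["mean_age", "cs_quota"],
                                      n_draws=50, seed=1)
        assert set(fit.names) == {"index", "mean_age", "cs_quota"}
        assert fit.elimination_log == []

    def test_elimination_log_aic_improves_each_step(self):
        f = self._frame(23)
        f["noise2"] = 0.0  # keep candidates to implemented names
        fit = metareg.fit_final_model(
            f, f["_index"], candidates=["mean_age", "prop_female",
                                        "combined_symptoms", "cs_quota"],
            n_draws=50, seed=1)
        for e in fit.elimination_log:
            assert e["aic_after"] < e["aic_before"]

    def test_empty_candidates_fits_index_only(self):
        f = self._frame(24)
        fit = metareg.fit_final_model(f, f["_index"], candidates=[],
                                      n_draws=50, seed=1)
        assert fit.names == ["index"]


class TestCombinedCoefficients:
    roles = {n: "indicator" for n in metareg.INDICATOR_NAMES}

    def test_constant_factors(self):
        step1 = make_coeffs({"mobility_decrease": 0.9, "sqrt_infection": 18.1,
                             "sqrt_excess": 0.0},
                            roles=self.roles, pvalues={"sqrt_excess": 0.9})
        step2 = make_coeffs({"index": 0.4}, roles={"index": "index"})
        combo = metareg.combined_indicator_coefficients(step1, step2)
        assert set(combo) == {"mobility_decrease", "sqrt_infection"}
        np.testing.assert_allclose(combo["sqrt_infection"], 7.24)

    def test_zero_factor_absorbs(self):
        step1 = make_coeffs({"mobility_decrease": 0.9, "sqrt_infection": 18.1,
                             "sqrt_excess": 0.0},
                            roles=self.roles, pvalues={"sqrt_excess": 0.9})
        step2 = make_coeffs({"index": 0.0}, roles={"index": "index"})
        combo = metareg.combined_indicator_coefficients(step1, step2)
        assert all(np.all(v == 0.0) for v in combo.values())

    def test_mean_of_products_differs_from_product_of_means(self):
        rng = np.random.default_rng(9)
        a = rng.normal(18.1, 5.0, 1000)
        b = a * 0.02 + rng.normal(0.4, 0.1, 1000)   # correlated draws
        step1 = make_coeffs({"mobility_decrease": 0.9, "sqrt_infection": 18.1,
                             "sqrt_excess": 0.0},
                            roles=self.roles, pvalues={"sqrt_excess": 0.9},
                            draws=np.column_stack([np.full(1000, 0.9), a,
                                                   np.zeros(1000)]))
        step2 = make_coeffs({"index": 0.4}, roles={"index": "index"},
                            draws=b[:, None])
        combo = metareg.combined_indicator_coefficients(step1, step2)
        assert combo["sqrt_infection"].mean() != pytest.approx(
            a.mean() * b.mean(), rel=1e-3)

    def test_draw_count_mismatch_fails(self):
        step1 = make_coeffs({"mobility_decrease": 0.9, "sqrt_infection": 18.1,
                             "sqrt_excess": 0.0},
                            roles=self.roles, pvalues={"sqrt_excess": 0.9},
                            n_draws=1000)
        step2 = make_coeffs({"index": 0.4}, roles={"index": "index"},
                            n_draws=500)
        with pytest.raises(ValueError, match="mismatch"):
            metareg.combined_indicator_coefficients(step1, step2)
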