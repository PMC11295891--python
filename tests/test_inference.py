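"""Mixed models, BIC Bayes factors, evidence categories, diagnostics, ACF."""

import numpy as np
import pandas as pd
import pytest

from pupillight import inference, synth
from pupillight.inference import (
    EvidenceResult,
    MixedPupilModel,
    categorize_evidence,
    log10_bayes_factor,
)


def lmm_frame(rng, n_part=15, n_obs=25, light_slope=-1.0, age_slope=0.0, sigma_u=0.3,
              sigma_e=0.3):
    ages = rng.uniform(18, 87, n_part)
    rows = []
    for i in range(n_part):
        u = rng.normal(0, sigma_u)
        light = rng.uniform(-1, 4, n_obs)
        pupil = 5.0 + light_slope * light + age_slope * ages[i] + u + rng.normal(0, sigma_e, n_obs)
        for j in range(n_obs):
            rows.append((f"P{i:02d}", ages[i], ("female", "male")[i % 2], light[j], pupil[j]))
    return pd.DataFrame(rows, columns=["participant_id", "age_years", "sex", "light", "pupil_mm"])


class TestMixedPupilModel:
    def test_slope_recovery_from_generator_truth(self):
        rng = np.random.default_rng(1)
        df = lmm_frame(rng, light_slope=-1.0)
        res = MixedPupilModel.from_formula(
            "pupil_mm ~ light + age_years + (1|participant_id) + (1|sex)", df
        ).fit()
        assert res.fe_params["light"] == pytest.approx(-1.0, abs=3 * res.bse["light"])
        assert res.converged

    def test_null_predictor_within_three_se_of_zero(self):
        rng = np.random.default_rng(2)
        df = lmm_frame(rng, age_slope=0.0)
        res = MixedPupilModel.from_formula(
            "pupil_mm ~ light + age_years + (1|participant_id) + (1|sex)", df
        ).fit()
        assert abs(res.fe_params["age_years"]) < 3 * res.bse["age_years"]

    def test_intercept_only_matches_closed_form_gaussian(self):
        """With no random structure the ML log-likelihood has a closed form:
        the Gaussian loglik at the pooled mean and the ML variance."""
        rng = np.random.default_rng(3)
        y = rng.normal(5.0, 0.7, 300)
        df = pd.DataFrame({"pupil_mm": y, "participant_id": "X", "g2": np.arange(300) % 2})
        res = MixedPupilModel.from_formula("pupil_mm ~ (1|g2)", df).fit()
        var_ml = y.var()
        loglik = -0.5 * y.size * (np.log(2 * np.pi * var_ml) + 1)
        # the g2 variance component collapses to ~0 on exchangeable data
        assert res.log_likelihood == pytest.approx(loglik, abs=0.05)
        assert res.boundary

    def test_parameter_recovery_rate_across_replicates(self):
        """Fixed-effect estimate within 2 SE of truth in >= 90% of replicates."""
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(10_000 + rep)
            df = lmm_frame(rng, n_part=8, n_obs=12, light_slope=-0.8)
            res = MixedPupilModel.from_formula(
                "pupil_mm ~ light + (1|participant_id)", df
            ).fit()
            if abs(res.fe_params["light"] - (-0.8)) <= 2 * res.bse["light"]:
                hits += 1
        assert hits >= 90

    def test_rank_deficient_design_names_terms(self):
        rng = np.random.default_rng(4)
        df = lmm_frame(rng)
        df["light_copy"] = df["light"]
        with pytest.raises(ValueError, match="light_copy"):
            MixedPupilModel.from_formula(
                "pupil_mm ~ light + light_copy + (1|participant_id)", df
            )

    def test_missing_columns_and_single_level_group(self):
        rng = np.random.default_rng(5)
        df = lmm_frame(rng)
        with pytest.raises(KeyError):
            MixedPupilModel.from_formula("pupil_mm ~ nope + (1|participant_id)", df)
        df1 = df[df.participant_id == "P00"]
        with pytest.raises(ValueError, match="levels"):
            MixedPupilModel.from_formula("pupil_mm ~ light + (1|participant_id)", df1)

    def test_summary_lists_terms(self):
        rng = np.random.default_rng(6)
        res = MixedPupilModel.from_formula(
            "pupil_mm ~ light + (1|participant_id)", lmm_frame(rng, 6, 10)
        ).fit()
        text = res.summary()
        assert "light" in text and "BIC" in text


class TestBayesFactor:
    @staticmethod
    def _fits(rng):
        df = lmm_frame(rng)
        full = MixedPupilModel.from_formula(
            "pupil_mm ~ light + age_years + (1|participant_id)", df
        ).fit()
        null = MixedPupilModel.from_formula(
            "pupil_mm ~ age_years + (1|participant_id)", df
        ).fit()
        mid = MixedPupilModel.from_formula(
            "pupil_mm ~ light + (1|participant_id)", df
        ).fit()
        return full, mid, null

    def test_identical_fit_gives_zero(self):
        rng = np.random.default_rng(7)
        full, *_ = self._fits(rng)
        ev = log10_bayes_factor(full, full)
        assert ev.log10_bf == 0.0
        assert ev.category == "no evidence"

    def test_bic_algebra(self):
        rng = np.random.default_rng(8)
        full, _, null = self._fits(rng)
        ev = log10_bayes_factor(full, null)
        assert ev.log10_bf == pytest.approx((null.bic - full.bic) / (2 * np.log(10)))

    def test_antisymmetry_and_additivity(self):
        rng = np.random.default_rng(9)
        full, mid, null = self._fits(rng)
        ab = log10_bayes_factor(full, mid).log10_bf
        bc = log10_bayes_factor(mid, null).log10_bf
        ac = log10_bayes_factor(full, null).log10_bf
        assert ac == pytest.approx(ab + bc, abs=1e-9)
        assert log10_bayes_factor(mid, full).log10_bf == pytest.approx(-ab, abs=1e-12)

    def test_mismatched_observation_sets_rejected(self):
        rng = np.random.default_rng(10)
        df = lmm_frame(rng)
        full = MixedPupilModel.from_formula("pupil_mm ~ light + (1|participant_id)", df).fit()
        null = MixedPupilModel.from_formula(
            "pupil_mm ~ light + (1|participant_id)", df.iloc[:-5]
        ).fit()
        with pytest.raises(ValueError, match="identical observation"):
            log10_bayes_factor(full, null)

    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.0, "no evidence"),
            (0.2, "anecdotal"),
            (np.log10(3.0), "anecdotal"),  # boundary -> weaker category
            (0.6, "moderate"),
            (1.0, "moderate"),  # BF exactly 10
            (1.2, "strong"),
            (np.log10(30.0), "strong"),
            (1.7, "very strong"),
            (2.0, "very strong"),
            (2.5, "decisive"),
            (-0.6, "null-moderate"),
            (-3.0, "null-decisive"),
        ],
    )
    def test_category_thresholds(self, value, expected):
        assert categorize_evidence(value) == expected

    def test_category_monotone_in_log10_bf(self):
        order = ["no evidence", "anecdotal", "moderate", "strong", "very strong", "decisive"]
        grid = np.linspace(0, 3, 301)
        ranks = [order.index(categorize_evidence(v)) for v in grid]
        assert all(a <= b for a, b in zip(ranks, ranks[1:]))

    def test_evidence_result_rejects_inconsistent_category(self):
        with pytest.raises(ValueError):
            EvidenceResult("x", 2.5, "moderate", "BIC approximation", 10, "a", "b")


class TestBatteries:
    def test_confirmatory_directions_on_effectful_generator(self, qc_field):
        ev = inference.run_confirmatory(qc_field)
        assert ev["CH1"].log10_bf > inference.LOG10_BF_DECISIVE
        assert ev["CH1"].category == "decisive"
        assert ev["CH3"].log10_bf > 0

    def test_ch3_null_when_age_effect_absent(self):
        rng = np.random.default_rng(20)
        df = lmm_frame(rng, age_slope=0.0)
        df["melanopic_edi_lx"] = 10.0 ** df.pop("light")
        df["illuminance_lx"] = df["melanopic_edi_lx"]
        ev = inference.run_confirmatory(df, condition=None)
        assert ev["CH3"].log10_bf < 0

    def test_ch2_small_when_predictors_carry_equal_information(self):
        rng = np.random.default_rng(21)
        df = lmm_frame(rng)
        df["melanopic_edi_lx"] = 10.0 ** df.pop("light")
        df["illuminance_lx"] = df["melanopic_edi_lx"] * 1.7  # proportional => same info
        ev = inference.run_confirmatory(df, condition=None)
        assert abs(ev["CH2"].log10_bf) < 0.5

    def test_ch2_decisive_on_dissociated_lab_spectra(self, small_cohort, clean_config):
        lab = synth.simulate_lab(small_cohort, clean_config, 30)
        ev = inference.run_confirmatory(lab, condition="lab")
        assert ev["CH2"].log10_bf > inference.LOG10_BF_DECISIVE

    def test_transform_check_prefers_generating_scale(self):
        rng = np.random.default_rng(22)
        log_df = lmm_frame(rng)  # pupil linear in log10 light over ~5 decades
        log_df["melanopic_edi_lx"] = 10.0 ** log_df.pop("light")
        assert inference.transform_check(log_df, condition=None).log10_bf > 0

        lin_df = lmm_frame(rng, light_slope=0.0)
        lin = rng.uniform(1.0, 3.0, len(lin_df))  # narrow range, linear response
        lin_df["melanopic_edi_lx"] = lin
        lin_df["pupil_mm"] = 6.0 - 1.0 * lin + rng.normal(0, 0.2, len(lin_df))
        assert inference.transform_check(lin_df, condition=None).log10_bf < 0

    def test_exploratory_nonpositive_under_null_generator(self, qc_field):
        ev = inference.run_exploratory(qc_field)
        assert all(e.log10_bf <= 0 for e in ev.values())

    def test_exploratory_detects_iris_effect(self):
        gen = synth.GeneratorConfig(
            iris_effect_mm={"blue": 0.5, "hazel/green": 0.0, "brown": -0.5},
            low_confidence_fraction=0.0, saturation_probability=0.0,
            misestimate_probability=0.0,
        )
        cohort = synth.sample_cohort(24, 313, gen)
        field = synth.simulate_field(cohort, 30, gen, 314)
        assert inference.run_exploratory(field)["EH2"].log10_bf > 0

    def test_exploratory_missing_covariates_rejected(self, qc_field):
        with pytest.raises(KeyError, match="covariates"):
            inference.run_exploratory(qc_field.drop(columns=["iris_colour"]))


class TestPredictorComparison:
    def test_matrix_antisymmetric_with_zero_diagonal(self, qc_field):
        m = inference.predictor_comparison(qc_field).to_numpy()
        assert np.allclose(np.diag(m), 0.0)
        assert np.allclose(m, -m.T, atol=1e-9)

    def test_duplicate_metrics_rejected(self, qc_field):
        with pytest.raises(ValueError, match="duplicate"):
            inference.predictor_comparison(
                qc_field, metrics=("melanopic_edi_lx", "melanopic_edi_lx")
            )

    def test_generating_metric_wins_single_comparison(self, small_cohort, clean_config):
        """On lab-style dissociated spectra the melanopic metric (which drives
        the generator's pupil) beats photopic illuminance."""
        lab = synth.simulate_lab(small_cohort, clean_config, 31)
        m = inference.predictor_comparison(
            lab, metrics=("melanopic_edi_lx", "illuminance_lx"), condition="lab"
        )
        assert m.loc["melanopic_edi_lx", "illuminance_lx"] > 0


class TestDiagnostics:
    def test_homoscedastic_linear_generator_flags_nothing(self):
        rng = np.random.default_rng(40)
        df = lmm_frame(rng, sigma_u=0.0, sigma_e=0.3)
        res = MixedPupilModel.from_formula("pupil_mm ~ light + (1|participant_id)", df).fit()
        d = inference.regression_diagnostics(res)
        assert abs(d["heteroscedasticity_slope"]) < 0.05
        assert abs(d["resid_fitted_curvature"]) < 0.05

    def test_log_response_to_linear_light_flags_curvature(self):
        rng = np.random.default_rng(41)
        n = 600
        medi = 10.0 ** rng.uniform(0, 4, n)
        pupil = 6.0 - 1.0 * np.log10(medi) + rng.normal(0, 0.1, n)
        df = pd.DataFrame(
            {"pupil_mm": pupil, "medi": medi, "participant_id": np.arange(n) % 5}
        )
        res = MixedPupilModel.from_formula("pupil_mm ~ medi + (1|participant_id)", df).fit()
        d = inference.regression_diagnostics(res)
        assert abs(d["resid_fitted_curvature"]) > 0.01

    def test_near_duplicate_predictor_blows_up_vif(self):
        rng = np.random.default_rng(42)
        df = lmm_frame(rng)
        df["light2"] = df["light"] + rng.normal(0, 1e-9, len(df))
        res = MixedPupilModel.from_formula(
            "pupil_mm ~ light + light2 + (1|participant_id)", df
        ).fit()
        d = inference.regression_diagnostics(res)
        assert d["vif"]["light"] > 1e6 or np.isinf(d["vif"]["light"])


class TestAutocorrelation:
    @staticmethod
    def _frame(values, pid="A"):
        return pd.DataFrame(
            {
                "participant_id": pid,
                "timestamp_s": np.arange(len(values)) * 10.0,
                "pupil_mm": values,
            }
        )

    def test_white_noise_acf_near_zero(self):
        rng = np.random.default_rng(50)
        acf = inference.autocorrelation(self._frame(rng.normal(size=2000)), 3)
        assert np.all(np.abs(acf["acf"]) < 0.08)

    def test_ar1_acf_matches_phi(self):
        rng = np.random.default_rng(51)
        x = np.zeros(3000)
        for t in range(1, x.size):
            x[t] = 0.8 * x[t - 1] + rng.normal()
        acf = inference.autocorrelation(self._frame(x), 2)
        assert acf["acf"].iloc[0] == pytest.approx(0.8, abs=0.05)
        assert acf["acf"].iloc[1] == pytest.approx(0.64, abs=0.07)

    def test_constant_series_flagged_undefined(self):
        acf = inference.autocorrelation(self._frame(np.full(50, 4.0)), 2)
        assert acf["acf"].isna().all()
        assert (acf["n_participants"] == 0).all()

    def test_gap_pairs_dropped(self):
        rng = np.random.default_rng(52)
        df = self._frame(rng.normal(size=100))
        df = df.drop(index=range(40, 60))  # 200 s gap
        acf = inference.autocorrelation(df, 2)
        assert np.isfinite(acf["acf"]).all()

    def test_excessive_lag_rejected(self):
        with pytest.raises(ValueError, match="max_lag"):
            inference.autocorrelation(self._frame(np.arange(10.0)), 10)
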