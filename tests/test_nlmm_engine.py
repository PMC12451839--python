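"""Mixed-model engine: exact degenerate recovery, LMM oracle agreement,
precision gating, criteria, empirical-Bayes behaviour, diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from braintraj import (
    DesignConfig,
    StructuralModelSpec,
    cv_percent,
    fit_nlmm,
    flag_out_of_range,
    individual_estimates,
    information_criteria,
    predicted_vs_observed,
    preset,
    simulate_cohort,
)
from braintraj.nlmm_engine import IndividualFit
from braintraj.structural_models import CovariateMap


class TestCvPercent:
    @pytest.mark.parametrize("estimate,se,expected", [
        (5089.72, 57.63, 1.13),    # printed lower-asymptote cell
        (-5.94, 0.72, 12.12),      # printed hill cell
        (1741.55, 37.01, 2.13),    # printed pallidum cell
        (4673.60, 66.7, 1.43),     # printed caudate intercept cell
    ])
    def test_reproduces_printed_cv_cells(self, estimate, se, expected):
        cv, gated = cv_percent(estimate, se)
        assert round(cv, 2) == expected
        assert gated

    def test_boundary_twenty_percent_fails_gate(self):
        cv, gated = cv_percent(10.0, 2.0)
        assert cv == 20.0 and not gated

    def test_zero_estimate_not_gateable(self):
        cv, gated = cv_percent(0.0, 1.0)
        assert np.isnan(cv) and not gated

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            cv_percent(1.0, -0.1)


class TestInformationCriteria:
    def test_formula(self):
        aic, bic = information_criteria(-100.0, 4, 90)
        assert aic == 208.0
        assert bic == pytest.approx(200 + 4 * np.log(90))

    def test_zero_parameters_edge(self):
        aic, bic = information_criteria(-50.0, 0, 90)
        assert aic == 100.0 and bic == 100.0

    def test_accepts_fit_object(self, caudate_linear_fit):
        aic, bic = information_criteria(caudate_linear_fit)
        assert aic == pytest.approx(caudate_linear_fit.aic)
        assert bic == pytest.approx(caudate_linear_fit.bic)

    def test_nested_model_likelihood_ordering(self, caudate_cohort):
        """The larger (covariate) model cannot have lower max likelihood."""
        ds, _ = caudate_cohort
        small = fit_nlmm(ds, "caudate", StructuralModelSpec("linear"))
        cmap = CovariateMap("linear", [("a", "sex", 0.0), ("b", "sex", 0.0)])
        big = fit_nlmm(ds, "caudate",
                       StructuralModelSpec("linear", None, cmap))
        assert big.loglik >= small.loglik - 1e-4


class TestFitting:
    def test_degenerate_noise_free_recovery_is_exact(self):
        m = preset("caudate", covariates=False)
        m.between_subject_sd = {"a": 0.0, "b": 0.0}
        m.residual_sd = 1e-6
        ds, _ = simulate_cohort(DesignConfig(seed=2, n_subjects=20), m,
                                seed=2)
        fit = fit_nlmm(ds, "caudate", StructuralModelSpec("linear"))
        assert abs(fit.estimate("a") / 4673.60 - 1) < 1e-4
        assert abs(fit.estimate("b") / -31.00 - 1) < 1e-4

    def test_linear_engine_agrees_with_standard_lmm(self, caudate_cohort):
        """Random-intercept linear fit vs the closed-form ML linear mixed
        model (independent implementation)."""
        ds, _ = caudate_cohort
        fit = fit_nlmm(ds, "caudate",
                       StructuralModelSpec("linear", random_effects=("a",)))
        df = ds.region_frame("caudate")
        ref = sm.MixedLM(df["volume"], sm.add_constant(df["age"]),
                         groups=df["subject_id"]).fit(reml=False)
        assert abs(fit.estimate("a") / ref.params["const"] - 1) < 1e-3
        assert abs(fit.estimate("b") / ref.params["age"] - 1) < 1e-3
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-3)

    def test_repeat_fit_is_bitwise_deterministic(self, caudate_cohort):
        ds, _ = caudate_cohort
        spec = StructuralModelSpec("linear")
        a = fit_nlmm(ds, "caudate", spec, seed=11)
        b = fit_nlmm(ds, "caudate", spec, seed=11)
        assert np.array_equal(a.estimates, b.estimates)
        assert a.loglik == b.loglik

    def test_logistic_initialization_resolves_swap_symmetry(self,
                                                            gm_logistic_fit):
        # declining volumes: hill negative, childhood plateau = upper asymptote
        assert gm_logistic_fit.estimate("hill") < 0
        assert gm_logistic_fit.estimate("a_upper") > \
            gm_logistic_fit.estimate("a_lower")

    def test_structural_cvs_are_precise_on_preset_cohort(self,
                                                         gm_logistic_fit):
        for p in ("a_lower", "a_upper", "inflection", "hill"):
            cv = gm_logistic_fit.cv_percent[
                gm_logistic_fit.param_labels.index(p)]
            assert np.isfinite(cv) and cv < 20.0

    def test_needs_two_subjects(self):
        ds, _ = simulate_cohort(DesignConfig(seed=1, n_subjects=1),
                                preset("caudate", covariates=False), seed=1)
        with pytest.raises(ValueError, match="2 subjects"):
            fit_nlmm(ds, "caudate", StructuralModelSpec("linear"))


class TestIndividualEstimates:
    def test_full_shrinkage_when_no_between_subject_variance(self):
        m = preset("caudate", covariates=False)
        m.between_subject_sd = {"a": 1e-6, "b": 1e-8}
        ds, _ = simulate_cohort(DesignConfig(seed=6, n_subjects=30), m,
                                seed=6)
        fit = fit_nlmm(ds, "caudate", StructuralModelSpec("linear"))
        ind = individual_estimates(fit)
        spread = ind.table["b"].std()
        assert spread < 0.05 * abs(fit.estimate("b"))

    def test_outlying_subject_pulls_its_eb_estimate(self, gm_cohort,
                                                    gm_logistic_fit):
        ds, truth = gm_cohort
        ind = individual_estimates(gm_logistic_fit)
        merged = truth.merge(ind.table, on="subject_id",
                             suffixes=("_true", "_eb"))
        top = merged.loc[merged["inflection_true"].idxmax()]
        pop = gm_logistic_fit.estimate("inflection")
        assert top["inflection_true"] > pop + 1.0
        assert top["inflection_eb"] > pop

    def test_eb_spread_reflects_generating_spread(self, gm_cohort,
                                                  gm_logistic_fit):
        """EB scalars are shrunk, so their SD is below the generating SD
        but correlates with the truth."""
        ds, truth = gm_cohort
        ind = individual_estimates(gm_logistic_fit)
        merged = truth.merge(ind.table, on="subject_id",
                             suffixes=("_true", "_eb"))
        r = np.corrcoef(merged["inflection_true"],
                        merged["inflection_eb"])[0, 1]
        assert r > 0.25  # per-subject timing is weakly identified at ~8 obs
        # conditional modes are shrunk: spread below the generating spread
        assert ind.table["inflection"].std() < truth["inflection"].std()


class TestDiagnostics:
    def test_well_specified_predictions_track_observations(self, gm_cohort,
                                                           gm_logistic_fit):
        diag = predicted_vs_observed(gm_logistic_fit)
        assert diag["slope"] == pytest.approx(1.0, abs=0.05)

    def test_misspecified_fit_loses_accuracy(self, gm_cohort):
        ds, _ = gm_cohort
        wrong = fit_nlmm(ds, "cortical_gm",
                         StructuralModelSpec("logarithmic"))
        right_sd = fit_nlmm(ds, "cortical_gm",
                            StructuralModelSpec("logistic")).residual_sd
        assert wrong.residual_sd > right_sd

    def test_clustering_index_bounded(self, gm_logistic_fit):
        c = predicted_vs_observed(gm_logistic_fit)["clustering_index"]
        assert 0.0 <= c <= 1.0


class TestOutOfRange:
    @staticmethod
    def _individual(scalars):
        table = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(len(scalars))],
            "sex": ["female"] * len(scalars),
            "n_obs": [3] * len(scalars),
            "inflection": scalars,
        })
        return IndividualFit("logistic", table, "inflection")

    def test_all_inside_gives_empty_list(self):
        ind = self._individual([14.0, 15.5, 18.0])
        assert flag_out_of_range(ind, (7.6, 21.6)).empty

    def test_early_inflection_flagged_with_observation_count(self):
        ind = self._individual([5.65, 14.0])
        out = flag_out_of_range(ind, (7.6, 21.6))
        assert list(out["subject_id"]) == ["s0"]
        assert out.loc[0, "scalar"] == 5.65
        assert out.loc[0, "n_obs"] == 3
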