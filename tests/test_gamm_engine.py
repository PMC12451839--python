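"""Penalized-smooth engine: basis/penalty structure, shape calls,
significance, stratified fits, and an external REML oracle."""

import subprocess
from types import SimpleNamespace

import numpy as np
import pytest

from braintraj import (
    SmoothSpec,
    build_basis,
    classify_shape,
    fit_gamm,
    smooth_significance,
    stratified_fits,
    write_long_table,
)
from braintraj.data_model import LongitudinalDataset


class TestBasis:
    ages = np.linspace(7.6, 21.6, 60)

    def test_constant_and_linear_are_penalty_free(self):
        X, S = build_basis(self.ages, 7)
        ones = np.ones(7)
        lin = np.arange(7.0)
        assert ones @ S @ ones == pytest.approx(0.0, abs=1e-12)
        assert lin @ S @ lin == pytest.approx(0.0, abs=1e-10)

    def test_linear_function_of_age_is_representable_and_penalty_free(self):
        X, S = build_basis(self.ages, 7)
        target = 2.0 + 3.0 * self.ages
        coef, res, *_ = np.linalg.lstsq(X, target, rcond=None)
        assert np.allclose(X @ coef, target, atol=1e-8)
        assert coef @ S @ coef == pytest.approx(0.0, abs=1e-8)

    def test_curvature_is_penalized(self):
        _, S = build_basis(self.ages, 7)
        quad = np.arange(7.0) ** 2
        assert quad @ S @ quad > 1.0

    def test_too_few_distinct_ages_errors(self):
        with pytest.raises(ValueError, match="reduce k"):
            build_basis(np.array([8.0, 9.0, 10.0, 8.0]), 7)

    def test_k_floor(self):
        with pytest.raises(ValueError):
            SmoothSpec(k=2)


class TestShape:
    def test_linear_truth_never_called_nonlinear(self, caudate_cohort):
        ds, _ = caudate_cohort
        fit = fit_gamm(ds, "caudate")
        call = classify_shape(fit)
        assert call.edf < 2.0
        assert call.classification in ("linear", "weakly nonlinear")

    def test_logistic_truth_yields_nonlinear_call(self, gm_full_cohort):
        ds, _ = gm_full_cohort
        fit = fit_gamm(ds, "cortical_gm")
        call = classify_shape(fit)
        assert call.edf > 2.0
        assert call.classification == "nonlinear"

    @pytest.mark.parametrize("edf,expected", [
        (1.0, "linear"),
        (1.05, "linear"),
        (1.7, "weakly nonlinear"),
        (5.55, "nonlinear"),
    ])
    def test_band_boundaries(self, edf, expected):
        fake = SimpleNamespace(edf={"s(age)": edf})
        assert classify_shape(fake).classification == expected

    def test_unknown_term_errors(self, caudate_cohort):
        ds, _ = caudate_cohort
        fit = fit_gamm(ds, "caudate")
        with pytest.raises(KeyError):
            classify_shape(fit, "s(nope)")


class TestSignificance:
    def test_strong_age_signal_is_significant(self, gm_full_cohort):
        ds, _ = gm_full_cohort
        fit = fit_gamm(ds, "cortical_gm")
        F, p = smooth_significance(fit, "s(age)")
        assert F > 10 and p < 0.001

    def test_sex_difference_smooth_detected_when_generated(self,
                                                           gm_full_cohort):
        """The generator shifts male timing by ~5 y; the difference smooth
        must pick that up."""
        ds, _ = gm_full_cohort
        fit = fit_gamm(ds, "cortical_gm")
        _, p = smooth_significance(fit, "s(age):sex")
        assert p < 0.01


class TestStratified:
    def test_single_sex_input_equals_whole_sample_fit(self, gm_full_cohort):
        ds, _ = gm_full_cohort
        df = ds.frame[ds.frame["sex"] == "female"]
        sub = LongitudinalDataset(df, validate=False)
        strat_f, _ = _safe_stratify(ds)
        solo = fit_gamm(sub, "cortical_gm",
                        SmoothSpec(by_sex=False, sex_effect=False))
        assert strat_f.edf["s(age)"] == pytest.approx(solo.edf["s(age)"],
                                                      abs=1e-6)
        assert np.allclose(strat_f.coefficients, solo.coefficients,
                           atol=1e-6)

    def test_sex_shifted_generator_orders_steepest_change(self,
                                                          gm_full_cohort):
        """Males are generated ~5 y later; their steepest-decline age must
        exceed the female one."""
        ds, _ = gm_full_cohort
        fit_f, fit_m = _safe_stratify(ds)
        assert _steepest_change_age(fit_m) > _steepest_change_age(fit_f)

    def test_missing_sex_errors(self, gm_full_cohort):
        ds, _ = gm_full_cohort
        df = ds.frame[ds.frame["sex"] == "female"]
        sub = LongitudinalDataset(df, validate=False)
        with pytest.raises(ValueError, match="male"):
            stratified_fits(sub, "cortical_gm")


def _safe_stratify(ds):
    return stratified_fits(ds, "cortical_gm")


def _steepest_change_age(fit):
    """Age of maximum |slope| of the fixed-effect trajectory, from a
    polynomial summary of the fitted curve."""
    age = fit.frame["age"].to_numpy(float)
    order = np.argsort(age)
    coefs = np.polyfit(age[order], fit.fixed_fitted[order], 5)
    grid = np.linspace(age.min() + 1, age.max() - 1, 200)
    slope = np.polyval(np.polyder(coefs), grid)
    return grid[np.argmax(np.abs(slope))]


class TestVarianceComponents:
    def test_random_intercept_absorbs_subject_offsets(self, gm_full_cohort):
        ds, _ = gm_full_cohort
        fit = fit_gamm(ds, "cortical_gm")
        # residual variance must be below the subject-offset-contaminated
        # spread of the fixed-effect residuals
        assert fit.sigma2 < np.var(fit.fixed_residuals)
        assert fit.sigma2_u > 0

    def test_random_slope_sensitivity_changes_edf_less_than_one(
            self, gm_full_cohort):
        ds, _ = gm_full_cohort
        base = fit_gamm(ds, "cortical_gm")
        slope = fit_gamm(ds, "cortical_gm", SmoothSpec(random_slope=True))
        assert abs(base.edf["s(age)"] - slope.edf["s(age)"]) < 1.0


class TestExternalOracle:
    def test_reml_fit_matches_mgcv_at_band_level(self, tmp_path,
                                                 gm_full_cohort):
        """Independent cross-check: the same model fit by mgcv must agree
        on the shape class, the random-intercept SD (within 20%), and the
        sex contrast (within 2 SEs)."""
        ds, _ = gm_full_cohort
        csv = tmp_path / "cohort.csv"
        write_long_table(ds, csv)
        script = tmp_path / "oracle.R"
        script.write_text(f"""
suppressMessages(library(mgcv))
d <- read.csv("{csv}")
d$sexo <- as.ordered(d$sex); contrasts(d$sexo) <- "contr.treatment"
d$subject_id <- factor(d$subject_id)
m <- gam(volume ~ sexo + s(age, k=7) + s(age, by=sexo, k=7)
         + s(subject_id, bs="re"), data=d, method="REML")
vc <- gam.vcomp(m)
cat(summary(m)$s.table["s(age)", "edf"], "\\n")
cat(vc["s(subject_id)", "std.dev"], "\\n")
cat(summary(m)$p.coeff["sexomale"], "\\n")
cat(summary(m)$se["sexomale"], "\\n")
""")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        lines = [ln for ln in out.stdout.strip().split("\n") if ln.strip()]
        edf_r, sd_u_r, sex_r, sex_se_r = map(float, lines[-4:])
        fit = fit_gamm(ds, "cortical_gm")
        assert (fit.edf["s(age)"] > 2.0) == (edf_r > 2.0)
        assert np.sqrt(fit.sigma2_u) == pytest.approx(sd_u_r, rel=0.2)
        sex_mine = float(
            fit.parametric.set_index("term").loc["sex", "estimate"])
        assert abs(sex_mine - sex_r) < 2 * sex_se_r
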