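"""Growth functions: printed-value checks, closed-form identities,
covariate application."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from braintraj import (
    CovariateMap,
    LogisticParams,
    eval_linear,
    eval_logarithmic,
    eval_logistic,
    individual_params,
)
from braintraj.structural_models import CovariateEntry

# published cortical grey matter group estimates (reporting scale /100)
GM = LogisticParams(a_lower=5089.72, a_upper=6105.41,
                    inflection=14.52, hill=-5.94)


class TestLogistic:
    def test_value_at_inflection_is_asymptote_midpoint(self):
        assert eval_logistic(GM, 14.52) == pytest.approx(5597.565, abs=1e-9)

    def test_childhood_value_matches_hand_evaluation(self):
        # 5089.72 + 1015.69 / (1 + (7/14.52)^5.94), evaluated by hand
        assert eval_logistic(GM, 7.0) == pytest.approx(6092.3, abs=0.1)

    def test_upper_asymptote_limit_for_positive_hill(self):
        assert eval_logistic((0.0, 1.0, 10.0, 4.0), 1e6) == \
            pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValueError):
            eval_logistic(GM, 0.0)
        with pytest.raises(ValueError):
            eval_logistic(GM, -3.0)

    def test_positive_inflection_required(self):
        with pytest.raises(ValueError):
            LogisticParams(0.0, 1.0, -2.0, 1.0)

    @settings(max_examples=200, derandomize=True)
    @given(al=st.floats(-1e4, 1e4), au=st.floats(-1e4, 1e4),
           infl=st.floats(0.1, 50.0), hill=st.floats(-20.0, 20.0))
    def test_midpoint_identity_holds_for_all_params(self, al, au, infl, hill):
        y = eval_logistic((al, au, infl, hill), infl)
        assert y == pytest.approx((al + au) / 2.0, abs=1e-8 * (1 + abs(al) + abs(au)))

    @settings(max_examples=100, derandomize=True)
    @given(al=st.floats(-1e3, 1e3), au=st.floats(-1e3, 1e3),
           infl=st.floats(1.0, 30.0),
           hill=st.floats(0.5, 10.0) | st.floats(-10.0, -0.5))
    def test_monotone_with_direction_set_by_hill_and_span(self, al, au, infl,
                                                          hill):
        x = np.linspace(0.5, 40.0, 50)
        y = eval_logistic((al, au, infl, hill), x)
        d = np.diff(y)
        direction = np.sign(hill * (au - al))
        assert np.all(direction * d >= -1e-9 * (1 + abs(au - al)))

    @settings(max_examples=100, derandomize=True)
    @given(al=st.floats(-1e3, 1e3), au=st.floats(-1e3, 1e3),
           infl=st.floats(1.0, 30.0), hill=st.floats(-10.0, 10.0),
           x=st.floats(0.5, 40.0))
    def test_asymptote_swap_with_hill_negation_is_invariant(self, al, au,
                                                            infl, hill, x):
        y1 = eval_logistic((al, au, infl, hill), x)
        y2 = eval_logistic((au, al, infl, -hill), x)
        assert y1 == pytest.approx(y2, abs=1e-8 * (1 + abs(al) + abs(au)))


class TestLogarithmicAndLinear:
    @pytest.mark.parametrize("params,x,expected", [
        ((5.0, 0.0), 3.7, 5.0),
        ((0.0, 1.0), 1.0, 0.0),
        ((2.0, 3.0), np.e, 5.0),
    ])
    def test_logarithmic_examples(self, params, x, expected):
        assert eval_logarithmic(params, x) == pytest.approx(expected)

    def test_logarithmic_domain(self):
        with pytest.raises(ValueError):
            eval_logarithmic((1.0, 1.0), 0.0)

    @pytest.mark.parametrize("params,x,expected", [
        ((4673.60, -31.00), 10.0, 4363.60),   # published caudate line
        ((0.0, 0.0), 5.0, 0.0),
        ((1.0, 2.0), 3.0, 7.0),
    ])
    def test_linear_examples(self, params, x, expected):
        assert eval_linear(params, x) == pytest.approx(expected)


class TestCovariateMap:
    def test_logistic_admits_at_most_eight_entries(self):
        entries = [(p, c, 0.0)
                   for p in ("a_lower", "a_upper", "inflection", "hill")
                   for c in ("sex", "euler")]
        cmap = CovariateMap("logistic", entries)
        assert len(cmap) == 8
        with pytest.raises(ValueError, match="at most 8"):
            cmap.add(CovariateEntry("hill", "software", 0.0))

    def test_linear_admits_at_most_four(self):
        entries = [(p, c, 0.0) for p in ("a", "b")
                   for c in ("sex", "euler")]
        cmap = CovariateMap("linear", entries)
        with pytest.raises(ValueError, match="at most 4"):
            cmap.add(CovariateEntry("b", "software", 0.0))

    def test_duplicate_pair_rejected(self):
        cmap = CovariateMap("linear", [("b", "sex", 0.0)])
        with pytest.raises(ValueError, match="duplicate"):
            cmap.add(CovariateEntry("b", "sex", 1.0))

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            CovariateMap("linear", [("inflection", "sex", 0.0)])


class TestIndividualParams:
    POP = np.array([5089.72, 6105.41, 14.52, -5.94])

    def test_reference_female_identity(self):
        cmap = CovariateMap("logistic", [("inflection", "sex", 4.92)])
        phi = individual_params(self.POP, {"sex": 0}, cmap)
        assert np.allclose(phi, self.POP)

    def test_male_sex_shift_on_inflection(self):
        cmap = CovariateMap("logistic", [("inflection", "sex", 4.92)])
        phi = individual_params(self.POP, {"sex": 1}, cmap)
        assert phi[2] == pytest.approx(19.44)

    def test_motion_shift_on_hill(self):
        cmap = CovariateMap("logistic", [("hill", "euler", 0.01)])
        phi = individual_params(self.POP, {"euler": -200.0}, cmap)
        assert phi[3] - self.POP[3] == pytest.approx(-2.0)

    def test_random_effect_added(self):
        phi = individual_params(self.POP, {}, None,
                                random_effect=[0, 0, 1.5, 0])
        assert phi[2] == pytest.approx(16.02)

    def test_missing_covariate_names_subject(self):
        cmap = CovariateMap("logistic", [("hill", "euler", 0.01)])
        with pytest.raises(KeyError, match="S09"):
            individual_params(self.POP, {"sex": 1}, cmap, subject="S09")
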