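"""Shared fixtures: small simulated cohorts and fits reused across tests.

Session scope keeps the number of mixed-model fits (the expensive part)
to a minimum; everything is seeded and deterministic.
"""

import warnings

import pytest

from braintraj import (
    DesignConfig,
    StructuralModelSpec,
    fit_nlmm,
    preset,
    simulate_cohort,
)
from braintraj.nlmm_engine import ConvergenceWarning


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def caudate_cohort():
    """Covariate-free linear-truth cohort (caudate preset), n=60."""
    ds, truth = simulate_cohort(
        DesignConfig(seed=11, n_subjects=60),
        preset("caudate", covariates=False), seed=11)
    return ds, truth


@pytest.fixture(scope="session")
def caudate_linear_fit(caudate_cohort):
    ds, _ = caudate_cohort
    return fit_nlmm(ds, "caudate", StructuralModelSpec("linear"), seed=11)


@pytest.fixture(scope="session")
def gm_cohort():
    """Covariate-free logistic-truth cohort (cortical GM preset), n=60."""
    ds, truth = simulate_cohort(
        DesignConfig(seed=7, n_subjects=60),
        preset("cortical_gm", covariates=False), seed=7)
    return ds, truth


@pytest.fixture(scope="session")
def gm_logistic_fit(gm_cohort):
    ds, _ = gm_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_nlmm(ds, "cortical_gm", StructuralModelSpec("logistic"),
                        seed=7)


@pytest.fixture(scope="session")
def gm_full_cohort():
    """Cortical GM cohort with the published sex/motion structure, n=90."""
    ds, truth = simulate_cohort(
        DesignConfig(seed=7), preset("cortical_gm"), seed=7)
    return ds, truth
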