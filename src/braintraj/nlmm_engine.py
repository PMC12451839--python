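"""Maximum-likelihood nonlinear mixed-effects estimation.

Any of the three structural growth functions can be fit with additive
Gaussian random effects on a configurable subset of its parameters
(diagonal covariance) plus additive covariate effects on parameters and a
constant additive residual error.  The marginal likelihood

    L(theta) = prod_i  integral  p(y_i | eta_i) p(eta_i)  d eta_i

is approximated per subject by the Laplace method at the conditional mode
of the random effects (exact when the mean function is linear in its
parameters, which makes the linear family an ordinary linear mixed model
and gives an independent closed-form cross-check).  The conditional modes
are found by a damped, batched Gauss-Newton inner loop; the outer
optimization runs L-BFGS-B on a scaled parameter vector with deterministic,
data-driven initialization, so repeated fits are bit-for-bit reproducible
and the logistic's asymptote-swap symmetry is resolved once by the sign of
the empirical age-volume rank correlation.

Standard errors come from the numerically differentiated observed
information of the Laplace log-likelihood; parameter precision is gated by
the coefficient of variation (CV = 100*SE/|estimate|, adequate when < 20).
Model comparison uses AIC/BIC with the Laplace log-likelihood, k = number
of fixed effects + covariate coefficients + random-effect variances + 1
residual variance, and BIC's sample size = number of subjects (the
effective sample size for between-subject parameters).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools import numdiff

from .data_model import LongitudinalDataset
from .structural_models import PARAM_NAMES, DERIVED_SCALAR, CovariateMap

__all__ = [
    "StructuralModelSpec",
    "PopulationFit",
    "IndividualFit",
    "fit_nlmm",
    "information_criteria",
    "cv_percent",
    "individual_estimates",
    "predicted_vs_observed",
    "flag_out_of_range",
    "ConvergenceWarning",
]


class ConvergenceWarning(UserWarning):
    pass


@dataclasses.dataclass
class StructuralModelSpec:
    """Which growth function, which random effects, which covariates."""

    function: str
    random_effects: tuple[str, ...] | None = None  # None -> all params
    covariate_map: CovariateMap | None = None
    error_model: str = "constant"

    def __post_init__(self):
        if self.function not in PARAM_NAMES:
            raise ValueError(f"unknown function {self.function!r}")
        names = PARAM_NAMES[self.function]
        if self.random_effects is None:
            self.random_effects = names
        self.random_effects = tuple(self.random_effects)
        if not self.random_effects:
            raise ValueError("random_effects must be nonempty")
        for p in self.random_effects:
            if p not in names:
                raise ValueError(f"unknown random-effect parameter {p!r}")
        if self.covariate_map is not None \
                and self.covariate_map.function != self.function:
            raise ValueError("covariate_map function mismatch")
        if self.error_model != "constant":
            raise ValueError("only the constant additive error model is supported")


@dataclasses.dataclass
class PopulationFit:
    """Population-level fit: fixed effects, precision, criteria, diagnostics."""

    spec: StructuralModelSpec
    region: str
    param_labels: list[str]          # structural params then covariate labels
    estimates: np.ndarray            # same order as param_labels
    standard_errors: np.ndarray
    cv_percent: np.ndarray           # 100*SE/|estimate|
    wald_p: dict                     # per covariate label
    omega: dict                      # random-effect variances per parameter
    residual_sd: float
    loglik: float
    aic: float
    bic: float
    n_subjects: int
    n_obs: int
    convergence: dict
    _internal: dict = dataclasses.field(default_factory=dict, repr=False)

    @property
    def k_params(self) -> int:
        return len(self.param_labels) + len(self.omega) + 1

    def estimate(self, label: str) -> float:
        return float(self.estimates[self.param_labels.index(label)])

    def se(self, label: str) -> float:
        return float(self.standard_errors[self.param_labels.index(label)])

    def structural_estimates(self) -> dict:
        names = PARAM_NAMES[self.spec.function]
        return {p: self.estimate(p) for p in names}

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.param_labels,
            "estimate": self.estimates,
            "se": self.standard_errors,
            "cv_percent": self.cv_percent,
            "p": [self.wald_p.get(lbl, np.nan) for lbl in self.param_labels],
        })


@dataclasses.dataclass
class IndividualFit:
    """Per-subject empirical-Bayes parameters (conditional modes)."""

    function: str
    table: pd.DataFrame     # subject_id, sex, n_obs, params..., scalar column
    scalar_name: str        # inflection (logistic) or b (log/linear)

    @property
    def scalars(self) -> pd.Series:
        return self.table.set_index("subject_id")[self.scalar_name]


# -- data preparation -------------------------------------------------------

def _covariate_column(df: pd.DataFrame, name: str) -> np.ndarray:
    """Numeric per-row covariate values (sex -> male indicator, software ->
    ordinal epoch index, others raw)."""
    if name == "sex":
        return (df["sex"].to_numpy() == "male").astype(float)
    if name == "software":
        labels = sorted(df["software"].astype(str).unique())
        lut = {s: float(i) for i, s in enumerate(labels)}
        return df["software"].astype(str).map(lut).to_numpy()
    if name not in df.columns:
        raise KeyError(f"covariate column {name!r} not in dataset")
    col = df[name].to_numpy(dtype=float)
    if np.isnan(col).all():
        raise ValueError(f"covariate {name!r} is all-missing")
    if np.isnan(col).any():
        bad = df.loc[np.isnan(col), "subject_id"].unique()[:5]
        raise ValueError(
            f"covariate {name!r} missing for subject(s) {list(bad)}")
    return col


@dataclasses.dataclass
class _Problem:
    """Prepared arrays for one region's fit."""

    function: str
    y: np.ndarray
    x: np.ndarray
    subj_rows: np.ndarray       # row -> subject index
    subject_ids: list
    n_per_subject: np.ndarray
    cov_values: np.ndarray      # (n_obs, n_cov)
    cov_param_idx: np.ndarray   # covariate entry -> structural param index
    random_idx: np.ndarray      # random-effect -> structural param index
    sexes: np.ndarray           # per subject


def _prepare(dataset: LongitudinalDataset, region: str,
             spec: StructuralModelSpec) -> _Problem:
    df = dataset.region_frame(region)
    names = PARAM_NAMES[spec.function]
    subject_ids = list(df["subject_id"].drop_duplicates())
    sid_lut = {s: i for i, s in enumerate(subject_ids)}
    subj_rows = df["subject_id"].map(sid_lut).to_numpy()
    if len(subject_ids) < 2:
        raise ValueError("need at least 2 subjects to fit a mixed model")
    entries = list(spec.covariate_map) if spec.covariate_map else []
    cov_values = (np.column_stack([_covariate_column(df, e.covariate)
                                   for e in entries])
                  if entries else np.empty((len(df), 0)))
    cov_param_idx = np.array([names.index(e.parameter) for e in entries], int)
    random_idx = np.array([names.index(p) for p in spec.random_effects], int)
    sexes = df.drop_duplicates("subject_id")["sex"].to_numpy()
    return _Problem(
        function=spec.function,
        y=df["volume"].to_numpy(float),
        x=df["age"].to_numpy(float),
        subj_rows=subj_rows,
        subject_ids=subject_ids,
        n_per_subject=np.bincount(subj_rows, minlength=len(subject_ids)),
        cov_values=cov_values,
        cov_param_idx=cov_param_idx,
        random_idx=random_idx,
        sexes=sexes,
    )


# -- vectorized mean function and gradient (per-row parameters) -------------

def _mean_grad(function: str, phi: np.ndarray, x: np.ndarray):
    """Mean and Jacobian w.r.t. structural params, rows = observations."""
    if function == "linear":
        a, b = phi[:, 0], phi[:, 1]
        return a + b * x, np.column_stack([np.ones_like(x), x])
    if function == "logarithmic":
        a, b = phi[:, 0], phi[:, 1]
        lx = np.log(x)
        return a + b * lx, np.column_stack([np.ones_like(x), lx])
    # logistic
    a_lower, a_upper = phi[:, 0], phi[:, 1]
    inflection = np.maximum(phi[:, 2], 1e-6)
    hill = phi[:, 3]
    logratio = np.log(x) - np.log(inflection)
    t = np.exp(np.clip(-hill * logratio, -500, 500))
    u = 1.0 / (1.0 + t)
    span = a_upper - a_lower
    mean = a_lower + span * u
    tu2 = t * u * u
    grad = np.column_stack([
        1.0 - u,
        u,
        -span * hill * tu2 / inflection,
        span * logratio * tu2,
    ])
    return mean, grad


def _phi_fixed(prob: _Problem, beta: np.ndarray, gamma: np.ndarray
               ) -> np.ndarray:
    """Per-observation parameter matrix before random effects."""
    phi = np.tile(beta, (len(prob.y), 1))
    for j in range(len(gamma)):
        phi[:, prob.cov_param_idx[j]] += gamma[j] * prob.cov_values[:, j]
    return phi


# -- Laplace marginal negative log-likelihood -------------------------------

class _Objective:
    """Laplace -loglik with warm-started batched inner Gauss-Newton."""

    def __init__(self, prob: _Problem, n_gamma: int,
                 inner_tol: float = 1e-9, inner_maxiter: int = 100):
        self.prob = prob
        self.n_gamma = n_gamma
        self.p = len(PARAM_NAMES[prob.function])
        self.q = len(prob.random_idx)
        self.m = len(prob.subject_ids)
        self.eta = np.zeros((self.m, self.q))
        self.inner_tol = inner_tol
        self.inner_maxiter = inner_maxiter

    def unpack(self, theta: np.ndarray):
        p, g, q = self.p, self.n_gamma, self.q
        beta = theta[:p]
        gamma = theta[p:p + g]
        omega_sd = np.exp(theta[p + g:p + g + q])
        sigma = float(np.exp(theta[-1]))
        return beta, gamma, omega_sd, sigma

    def _g_per_subject(self, eta, phi_fix, sigma2, omega2):
        prob = self.prob
        with np.errstate(over="ignore", invalid="ignore"):
            phi = phi_fix.copy()
            phi[:, prob.random_idx] += eta[prob.subj_rows]
            mean, grad = _mean_grad(prob.function, phi, prob.x)
            r = np.clip(prob.y - mean, -1e120, 1e120)
            rss = np.bincount(prob.subj_rows, weights=r * r, minlength=self.m)
            g = rss / (2.0 * sigma2) + 0.5 * np.sum(eta * eta / omega2, axis=1)
        return g, r, grad

    def _hessian(self, grad, sigma2, omega2):
        """Per-subject Gauss-Newton Hessians J'J/sigma^2 + Omega^-1."""
        prob = self.prob
        J = grad[:, prob.random_idx]
        JTJ = np.zeros((self.m, self.q, self.q))
        np.add.at(JTJ, prob.subj_rows, J[:, :, None] * J[:, None, :])
        H = JTJ / sigma2
        H[:, np.arange(self.q), np.arange(self.q)] += 1.0 / omega2
        return H

    def inner(self, beta, gamma, omega_sd, sigma):
        """Conditional modes of eta by damped batched Gauss-Newton."""
        prob = self.prob
        sigma2 = sigma * sigma
        omega2 = np.maximum(omega_sd * omega_sd, 1e-300)
        phi_fix = _phi_fixed(prob, beta, gamma)
        eta = self.eta.copy()
        g, r, grad = self._g_per_subject(eta, phi_fix, sigma2, omega2)
        if not np.all(np.isfinite(g)):
            eta = np.zeros_like(eta)
            g, r, grad = self._g_per_subject(eta, phi_fix, sigma2, omega2)
        for _ in range(self.inner_maxiter):
            J = grad[:, prob.random_idx]
            JTr = np.zeros((self.m, self.q))
            np.add.at(JTr, prob.subj_rows, J * r[:, None])
            H = self._hessian(grad, sigma2, omega2)
            grad_eta = -JTr / sigma2 + eta / omega2
            try:
                delta = np.linalg.solve(H, grad_eta[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                return None, None, None
            step = np.ones(self.m)
            eta_new = eta - delta
            g_new, _, _ = self._g_per_subject(eta_new, phi_fix, sigma2, omega2)
            for _halve in range(15):
                worse = ~(g_new <= g + 1e-12)
                if not worse.any():
                    break
                step[worse] *= 0.5
                eta_new[worse] = eta[worse] - step[worse, None] * delta[worse]
                g_new, _, _ = self._g_per_subject(
                    eta_new, phi_fix, sigma2, omega2)
            still_worse = ~(g_new <= g + 1e-12)
            eta_new[still_worse] = eta[still_worse]
            move = float(np.max(np.abs(eta_new - eta))) if self.q else 0.0
            eta = eta_new
            g, r, grad = self._g_per_subject(eta, phi_fix, sigma2, omega2)
            scale = float(np.max(np.abs(eta))) + float(np.max(omega_sd)) + 1e-12
            if move <= self.inner_tol * scale:
                break
        self.eta = eta
        H = self._hessian(grad, sigma2, omega2)
        return eta, g, H

    def __call__(self, theta: np.ndarray) -> float:
        if not np.all(np.isfinite(theta)):
            return 1e12
        beta, gamma, omega_sd, sigma = self.unpack(theta)
        eta, g, H = self.inner(beta, gamma, omega_sd, sigma)
        if eta is None:
            return 1e12
        sign, logdetH = np.linalg.slogdet(H)
        if np.any(sign <= 0):
            return 1e12
        n = self.prob.n_per_subject
        # -log L_i = (n_i/2) log(2 pi s^2) + 0.5 log|Omega| + g(eta_hat)
        #            + 0.5 log|H_i|   (the (2 pi)^{q/2} factors cancel)
        nll = float(
            np.sum(n) * 0.5 * np.log(2 * np.pi * sigma * sigma)
            + self.m * np.sum(np.log(omega_sd * omega_sd)) * 0.5
            + np.sum(g)
            + 0.5 * np.sum(logdetH)
        )
        if not np.isfinite(nll):
            return 1e12
        return nll


# -- initialization ---------------------------------------------------------

def _initialize(prob: _Problem, spec: StructuralModelSpec):
    y, x = prob.y, prob.x
    names = PARAM_NAMES[spec.function]
    if spec.function == "logistic":
        rho = stats.spearmanr(x, y).statistic
        hill0 = 4.0 if rho >= 0 else -4.0
        beta = np.array([float(np.min(y)), float(np.max(y)),
                         float(np.median(x)), hill0])
    elif spec.function == "logarithmic":
        X = np.column_stack([np.ones_like(x), np.log(x)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    else:
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    gamma = np.zeros(len(prob.cov_param_idx))
    yscale = float(np.std(y)) + 1e-9
    omega0 = []
    for p in spec.random_effects:
        b = abs(beta[names.index(p)])
        omega0.append(max(0.1 * b, 1e-3 * yscale, 1e-8))
    phi = _phi_fixed(prob, np.asarray(beta, float), gamma)
    mean, _ = _mean_grad(spec.function, phi, x)
    sigma0 = max(float(np.std(y - mean)) * 0.5, 1e-6 * yscale, 1e-12)
    theta0 = np.concatenate([beta, gamma,
                             np.log(omega0), [np.log(sigma0)]])
    return theta0


# -- public operations ------------------------------------------------------

def cv_percent(estimate: float, se: float):
    """Coefficient of variation, 100*SE/|estimate|, with the <20% gate.

    Returns ``(cv, gated)``; the gate passes only for CV strictly below 20.
    A zero estimate has no defined CV and is reported as not gateable
    (``(nan, False)``).
    """
    if se < 0:
        raise ValueError("se must be nonnegative")
    if estimate == 0:
        return float("nan"), False
    cv = 100.0 * se / abs(estimate)
    return cv, bool(cv < 20.0)


def information_criteria(loglik, k: int | None = None,
                         n_subjects: int | None = None):
    """AIC = -2 loglik + 2k; BIC = -2 loglik + k ln(n_subjects).

    Accepts either a :class:`PopulationFit` or the raw
    ``(loglik, k, n_subjects)`` triple.  ``k`` counts fixed effects +
    covariate coefficients + random-effect variances + the residual
    variance; ``n_subjects`` is the effective sample size for BIC.
    """
    if isinstance(loglik, PopulationFit):
        fit = loglik
        loglik, k, n_subjects = fit.loglik, fit.k_params, fit.n_subjects
    if not np.isfinite(loglik):
        raise ValueError("log-likelihood must be finite")
    aic = -2.0 * loglik + 2.0 * k
    bic = -2.0 * loglik + k * np.log(n_subjects)
    return float(aic), float(bic)


def fit_nlmm(dataset: LongitudinalDataset, region: str,
             spec: StructuralModelSpec, seed: int = 0,
             maxiter: int = 400) -> PopulationFit:
    """Fit a nonlinear mixed-effects model for one region.

    The optimizer and initialization are fully deterministic; ``seed`` is
    accepted for interface stability (a stochastic algorithm could be
    substituted behind the same contract) and recorded in the diagnostics.
    Non-convergence raises a :class:`ConvergenceWarning` and is flagged in
    ``fit.convergence`` — it is never silently accepted.
    """
    prob = _prepare(dataset, region, spec)
    names = PARAM_NAMES[spec.function]
    obj = _Objective(prob, n_gamma=len(prob.cov_param_idx))
    theta0 = _initialize(prob, spec)

    # Parameter scaling: structural params by their own magnitude, covariate
    # coefficients by (attached parameter magnitude / covariate spread), the
    # log-variance components by unity (already on a natural scale).
    scale = np.ones_like(theta0)
    scale[:len(names)] = np.maximum(np.abs(theta0[:len(names)]), 1e-2)
    for j in range(len(prob.cov_param_idx)):
        target = np.abs(theta0[prob.cov_param_idx[j]])
        spread = float(np.std(prob.cov_values[:, j]))
        scale[len(names) + j] = max(0.2 * target, 1e-2) / max(spread, 1e-6)

    def f_scaled(z):
        return obj(theta0 + scale * z)

    # L-BFGS-B with restarts: between rounds the mean of the conditional
    # modes is folded into the fixed effects (random effects recentred),
    # which pulls the optimizer out of the flat valley where a constant
    # shift trades off between beta and the eta's.
    z = np.zeros_like(theta0)
    random_pos = [names.index(p) for p in spec.random_effects]
    nll_prev = np.inf
    nfev_total = 0
    for _round in range(3):
        res = optimize.minimize(
            f_scaled, z, method="L-BFGS-B",
            options={"maxiter": maxiter, "maxfun": 20 * maxiter,
                     "ftol": 1e-10, "gtol": 1e-6, "eps": 1e-6})
        nfev_total += int(res.nfev)
        z = res.x
        if not np.isfinite(res.fun) or res.fun >= nll_prev - 1e-7 * (
                1.0 + abs(res.fun)):
            break
        nll_prev = res.fun
        theta_cur = theta0 + scale * z
        beta_c, gamma_c, omega_c, sigma_c = obj.unpack(theta_cur)
        eta_c, _, _ = obj.inner(beta_c, gamma_c, omega_c, sigma_c)
        if eta_c is None:
            break
        mean_eta = eta_c.mean(axis=0)
        # only worth a restart when the modes are materially off-centre
        if np.max(np.abs(mean_eta) / (omega_c + 1e-300)) <= 0.25:
            break
        theta_cur = theta_cur.copy()
        theta_cur[random_pos] += mean_eta
        obj.eta = eta_c - mean_eta[None, :]
        z = (theta_cur - theta0) / scale
    theta_hat = theta0 + scale * res.x
    nll = obj(theta_hat)
    beta, gamma, omega_sd, sigma = obj.unpack(theta_hat)

    converged = bool(res.success) and np.isfinite(nll)
    if not converged:
        warnings.warn(
            f"NLMM fit for region {region!r} ({spec.function}) did not "
            f"converge: {res.message}", ConvergenceWarning, stacklevel=2)

    # observed information (numeric Hessian in scaled space, un-scaled)
    se_full = np.full(theta_hat.size, np.nan)
    se_available = False
    for eps in (1e-4, 5e-4, 2e-5):
        try:
            Hz = numdiff.approx_hess3(res.x, f_scaled, epsilon=eps)
            H = Hz / np.outer(scale, scale)
            cov = np.linalg.inv(H)
            diag = np.diag(cov)
        except np.linalg.LinAlgError:
            continue
        if np.all(np.isfinite(diag)) and \
                np.all(diag[:len(names) + len(gamma)] > 0):
            se_full = np.sqrt(np.maximum(diag, 0))
            se_available = True
            break
    if not se_available:
        warnings.warn(
            f"information matrix singular for region {region!r}; standard "
            "errors unavailable", ConvergenceWarning, stacklevel=2)

    cov_labels = spec.covariate_map.labels() if spec.covariate_map else []
    labels = list(names) + cov_labels
    estimates = np.concatenate([beta, gamma])
    ses = se_full[:len(labels)]
    cvs = np.array([cv_percent(e, s)[0] if np.isfinite(s) else np.nan
                    for e, s in zip(estimates, ses)])
    wald = {}
    for j, lbl in enumerate(cov_labels):
        est, se = gamma[j], ses[len(names) + j]
        wald[lbl] = (float(2 * stats.norm.sf(abs(est) / se))
                     if np.isfinite(se) and se > 0 else np.nan)

    loglik = -nll
    k = len(labels) + len(spec.random_effects) + 1
    aic, bic = information_criteria(loglik, k, len(prob.subject_ids))

    fit = PopulationFit(
        spec=spec, region=region, param_labels=labels,
        estimates=estimates, standard_errors=ses, cv_percent=cvs,
        wald_p=wald,
        omega={p: float(omega_sd[j] ** 2)
               for j, p in enumerate(spec.random_effects)},
        residual_sd=float(sigma), loglik=float(loglik),
        aic=aic, bic=bic,
        n_subjects=len(prob.subject_ids), n_obs=len(prob.y),
        convergence={
            "converged": converged, "message": str(res.message),
            "n_outer_evals": int(nfev_total), "seed": seed,
            "se_available": se_available,
            "algorithm": "Laplace / L-BFGS-B",
        },
        _internal={"problem": prob, "objective": obj,
                   "theta": theta_hat, "beta": beta, "gamma": gamma,
                   "omega_sd": omega_sd},
    )
    return fit


def individual_estimates(fit: PopulationFit,
                         dataset: LongitudinalDataset | None = None
                         ) -> IndividualFit:
    """Per-subject empirical-Bayes parameters (conditional modes).

    Subjects with few observations are shrunk toward their covariate-
    adjusted population values; the derived scalar is the inflection point
    for the logistic and the rate parameter ``b`` otherwise.  The reported
    per-subject parameter vector evaluates visit-varying covariates (motion)
    at the subject's mean value.
    """
    prob: _Problem = fit._internal["problem"]
    obj: _Objective = fit._internal["objective"]
    beta = fit._internal["beta"]
    gamma = fit._internal["gamma"]
    omega_sd = fit._internal["omega_sd"]
    sigma = fit.residual_sd
    eta, _, _ = obj.inner(beta, gamma, omega_sd, sigma)
    if eta is None:
        raise RuntimeError("conditional-mode solve failed")

    names = PARAM_NAMES[fit.spec.function]
    # subject-level covariate part: average the per-row fixed phi by subject
    phi_fix = _phi_fixed(prob, beta, gamma)
    phi_subj = np.zeros((len(prob.subject_ids), len(names)))
    for j in range(len(names)):
        phi_subj[:, j] = (np.bincount(prob.subj_rows, weights=phi_fix[:, j],
                                      minlength=len(prob.subject_ids))
                          / prob.n_per_subject)
    phi_subj[:, prob.random_idx] += eta

    table = pd.DataFrame({"subject_id": prob.subject_ids, "sex": prob.sexes,
                          "n_obs": prob.n_per_subject})
    for j, p in enumerate(names):
        table[p] = phi_subj[:, j]
    scalar = DERIVED_SCALAR[fit.spec.function]
    return IndividualFit(function=fit.spec.function, table=table,
                         scalar_name=scalar)


def predicted_vs_observed(fit: PopulationFit,
                          individual: IndividualFit | None = None,
                          dataset: LongitudinalDataset | None = None
                          ) -> dict:
    """Population and individual predictions with goodness-of-fit summary.

    Returns a dict with the per-observation table, the OLS slope/intercept
    of observed ~ individual predictions, and a threshold-free clustering
    index: the between-cluster share of prediction variance under the best
    two-group split of the population predictions (near 1 when predictions
    collapse onto two blobs, the failure mode the diagnostic looks for).
    """
    prob: _Problem = fit._internal["problem"]
    obj: _Objective = fit._internal["objective"]
    beta, gamma = fit._internal["beta"], fit._internal["gamma"]
    omega_sd = fit._internal["omega_sd"]

    phi_pop = _phi_fixed(prob, beta, gamma)
    pop_pred, _ = _mean_grad(prob.function, phi_pop, prob.x)

    eta, _, _ = obj.inner(beta, gamma, omega_sd, fit.residual_sd)
    phi_ind = phi_pop.copy()
    phi_ind[:, prob.random_idx] += eta[prob.subj_rows]
    ind_pred, _ = _mean_grad(prob.function, phi_ind, prob.x)

    slope, intercept = np.polyfit(ind_pred, prob.y, 1)
    table = pd.DataFrame({
        "subject_id": np.asarray(prob.subject_ids)[prob.subj_rows],
        "age": prob.x, "observed": prob.y,
        "population_pred": pop_pred, "individual_pred": ind_pred,
    })
    return {
        "table": table,
        "slope": float(slope),
        "intercept": float(intercept),
        "clustering_index": _two_group_variance_ratio(pop_pred),
    }


def _two_group_variance_ratio(values: np.ndarray) -> float:
    """Between-group share of variance for the best single split (exact 1D
    2-means).  0 for a single tight cluster relative spread; -> 1 for two
    separated blobs."""
    v = np.sort(np.asarray(values, float))
    n = len(v)
    total = np.var(v) * n
    if total <= 0 or n < 2:
        return 0.0
    csum = np.cumsum(v)
    best = 0.0
    for i in range(1, n):
        m1, m2 = csum[i - 1] / i, (csum[-1] - csum[i - 1]) / (n - i)
        between = i * (m1 - v.mean()) ** 2 + (n - i) * (m2 - v.mean()) ** 2
        best = max(best, between)
    return float(best / total)


def flag_out_of_range(individual: IndividualFit,
                      age_range: tuple[float, float]) -> pd.DataFrame:
    """Subjects whose derived age-like scalar falls outside the observed
    age range, with observation counts attached (sparse subjects — three or
    fewer observations — are the usual suspects)."""
    lo, hi = age_range
    t = individual.table
    mask = (t[individual.scalar_name] < lo) | (t[individual.scalar_name] > hi)
    out = t.loc[mask, ["subject_id", "sex", "n_obs",
                       individual.scalar_name]].copy()
    out = out.rename(columns={individual.scalar_name: "scalar"})
    return out.reset_index(drop=True)
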