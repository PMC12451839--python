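"""Per-region analysis orchestration.

For one region the full analysis runs: shape discovery with the penalized
smooth model, all three candidate structural mixed models, BIC model-family
selection, a (transferable) forward-stepwise covariate structure,
individual empirical-Bayes maturational parameters with per-sex summaries,
CV precision gating, out-of-range flags, baseline-vs-change correlations,
and three sensitivity refits.  Every number in the resulting report is the
output of one of the underlying module operations.

Model-family selection note: candidate structural models are fit regardless
of the shape call (a nonlinear smooth and a best-fitting linear structural
model can coexist, and do for several subcortical regions); the report
records the shape-conditional logic without enforcing it.  When AIC and BIC
disagree, BIC decides and the disagreement is logged.  No multiple-testing
correction is applied anywhere; p-values are reported raw.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import LongitudinalDataset, rescale_volumes
from .structural_models import DERIVED_SCALAR, PARAM_NAMES, CovariateMap
from .gamm_engine import SmoothSpec, classify_shape, fit_gamm
from .nlmm_engine import (
    IndividualFit,
    PopulationFit,
    StructuralModelSpec,
    fit_nlmm,
    flag_out_of_range,
    individual_estimates,
    predicted_vs_observed,
)

__all__ = [
    "PipelineConfig",
    "RegionReport",
    "StepwiseTrace",
    "select_structural_model",
    "stepwise_covariates",
    "run_region_analysis",
    "summarize_individual_differences",
    "correlate_baseline_change",
    "sensitivity_suite",
    "PAPER_COVARIATES",
]

#: The published covariate structure, transferable to every region: sex on
#: all structural parameters plus motion (Euler) on the slope-like one.
PAPER_COVARIATES = {
    "logistic": [("a_lower", "sex"), ("a_upper", "sex"),
                 ("inflection", "sex"), ("hill", "sex"), ("hill", "euler")],
    "logarithmic": [("b", "sex"), ("b", "euler")],
    "linear": [("a", "sex"), ("b", "sex")],
}

#: Regions whose volumes are rescaled (/100) before structural fitting.
RESCALED_REGIONS = ("cortical_gm", "white_matter")

CANDIDATE_FUNCTIONS = ("logistic", "logarithmic", "linear")


@dataclasses.dataclass
class PipelineConfig:
    use_covariates: bool = True
    candidate_functions: tuple[str, ...] = CANDIDATE_FUNCTIONS
    smooth: SmoothSpec = dataclasses.field(default_factory=SmoothSpec)
    run_sensitivity: bool = False
    rescale_divisor: float = 100.0
    stepwise: bool = False          # re-tune covariates per region vs transfer


@dataclasses.dataclass
class StepwiseTrace:
    steps: pd.DataFrame           # candidate, bic_before, bic_after, accepted
    final_map: CovariateMap
    base_bic: float


@dataclasses.dataclass
class RegionReport:
    region: str
    shape: object                       # ShapeCall
    gamm_parametric: pd.DataFrame
    gamm_smooths: pd.DataFrame
    criteria: pd.DataFrame              # per candidate: aic, bic, converged
    selected_function: str
    selection_note: str
    population: PopulationFit
    individual: IndividualFit
    individual_summary: dict
    cv_gates: dict
    out_of_range: pd.DataFrame
    diagnostics: dict
    correlations: dict
    sensitivity: dict | None
    provenance: dict

    def to_dict(self) -> dict:
        """Nested key-value serialization of the report."""
        pop = self.population
        return {
            "region": self.region,
            "shape": {"classification": self.shape.classification,
                      "edf": self.shape.edf},
            "criteria": self.criteria.to_dict("records"),
            "selected_function": self.selected_function,
            "selection_note": self.selection_note,
            "population": {
                "labels": pop.param_labels,
                "estimates": pop.estimates.tolist(),
                "se": pop.standard_errors.tolist(),
                "cv_percent": pop.cv_percent.tolist(),
                "wald_p": pop.wald_p,
                "omega": pop.omega,
                "residual_sd": pop.residual_sd,
                "loglik": pop.loglik, "aic": pop.aic, "bic": pop.bic,
            },
            "individual_summary": self.individual_summary,
            "cv_gates": self.cv_gates,
            "out_of_range": self.out_of_range.to_dict("records"),
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if k != "table"},
            "correlations": self.correlations,
            "sensitivity": self.sensitivity,
            "provenance": self.provenance,
        }


# -- model-family selection -------------------------------------------------

def select_structural_model(fits: dict) -> tuple[str, pd.DataFrame, str]:
    """Pick the function minimizing BIC among converged candidate fits.

    Returns (selected name, criteria table, note).  When AIC and BIC
    disagree about the winner, BIC decides and the note records it.
    """
    rows = []
    for name, fit in fits.items():
        rows.append((name, fit.aic, fit.bic,
                     bool(fit.convergence["converged"])))
    table = pd.DataFrame(rows, columns=["function", "aic", "bic", "converged"])
    ok = table[table["converged"]]
    if ok.empty:
        raise RuntimeError("no converged candidate fits to select from")
    by_bic = ok.loc[ok["bic"].idxmin(), "function"]
    by_aic = ok.loc[ok["aic"].idxmin(), "function"]
    note = ("AIC and BIC agree" if by_aic == by_bic else
            f"AIC prefers {by_aic}, BIC prefers {by_bic}; BIC decides")
    return by_bic, table, note


# -- forward-stepwise covariate selection -----------------------------------

def stepwise_covariates(dataset: LongitudinalDataset, region: str,
                        function: str, candidates: list[tuple[str, str]],
                        seed: int = 0,
                        random_effects: tuple[str, ...] | None = None
                        ) -> StepwiseTrace:
    """Greedy forward selection of (parameter, covariate) entries by BIC.

    Each round fits every remaining single-entry addition; the best is
    accepted only if it strictly improves BIC.  Deterministic under seed.
    """
    names = PARAM_NAMES[function]
    for p, c in candidates:
        if p not in names:
            raise ValueError(f"unknown parameter {p!r} for {function}")
    limit = 8 if function == "logistic" else 4
    if len(candidates) > limit:
        raise ValueError(
            f"{function} admits at most {limit} covariate entries")

    current: list[tuple[str, str]] = []
    base = fit_nlmm(dataset, region,
                    StructuralModelSpec(function, random_effects,
                                        _as_map(function, current)), seed)
    best_bic = base.bic
    base_bic = base.bic
    remaining = list(candidates)
    rows = []
    while remaining:
        trial_bics = []
        for cand in remaining:
            spec = StructuralModelSpec(
                function, random_effects,
                _as_map(function, current + [cand]))
            fit = fit_nlmm(dataset, region, spec, seed)
            trial_bics.append(fit.bic)
        j = int(np.argmin(trial_bics))
        accepted = trial_bics[j] < best_bic
        rows.append((f"{remaining[j][1]}({remaining[j][0]})",
                     best_bic, trial_bics[j], accepted))
        if not accepted:
            break
        current.append(remaining.pop(j))
        best_bic = trial_bics[j]
    steps = pd.DataFrame(
        rows, columns=["candidate", "bic_before", "bic_after", "accepted"])
    return StepwiseTrace(steps=steps, final_map=_as_map(function, current),
                         base_bic=base_bic)


def _as_map(function: str, entries: list[tuple[str, str]]) -> CovariateMap:
    return CovariateMap(function, [(p, c, 0.0) for p, c in entries])


# -- summaries --------------------------------------------------------------

def summarize_individual_differences(individual: IndividualFit,
                                     by_sex: bool = True) -> dict:
    """Min/max/range/mean and density-ready quantiles of the derived
    per-subject scalar (maturational timing or rate), optionally per sex."""
    s = individual.table[individual.scalar_name]
    if len(s) == 0:
        raise ValueError("no subjects in individual fit")
    out = {
        "scalar": individual.scalar_name,
        "n": int(len(s)),
        "min": float(s.min()),
        "max": float(s.max()),
        "range": float(s.max() - s.min()),
        "mean": float(s.mean()),
        "sd": float(s.std(ddof=1)) if len(s) > 1 else 0.0,
        "quantiles": {f"q{int(q * 100):02d}": float(s.quantile(q))
                      for q in (0.05, 0.25, 0.5, 0.75, 0.95)},
    }
    if by_sex:
        means = individual.table.groupby("sex")[individual.scalar_name].mean()
        out["by_sex_mean"] = {k: float(v) for k, v in means.items()}
    return out


def correlate_baseline_change(individual: IndividualFit, baseline_param: str,
                              change_param: str):
    """Pearson correlation between individual baseline-level estimates and
    |change| estimates; returns (r, df, p) with df = n - 2.

    Absolute values are taken for the change parameter (hill or slope) so
    the correlation reads as baseline level vs magnitude of change.
    """
    t = individual.table
    if len(t) < 3:
        raise ValueError("need at least 3 subjects for a correlation")
    x = t[baseline_param].to_numpy(float)
    y = np.abs(t[change_param].to_numpy(float))
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), len(t) - 2, float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), len(t) - 2, float(p)


# -- sensitivity suite ------------------------------------------------------

def sensitivity_suite(dataset: LongitudinalDataset, region: str,
                      main_fit: PopulationFit,
                      config: PipelineConfig | None = None,
                      seed: int = 0) -> dict:
    """Three refit arms, each reporting deltas against the main model.

    (a) structural model with an empty covariate map;
    (b) smooth model with eTIV as an extra parametric main effect;
    (c) smooth model with software as a main effect, and the structural
        model with software as a covariate on the parameter of interest.
    Arms needing a column the data lacks are skipped with a notice.
    """
    config = config or PipelineConfig()
    function = main_fit.spec.function
    scalar = DERIVED_SCALAR[function]
    df = dataset.region_frame(region)
    out: dict = {"notes": []}

    # (a) no-covariate refit
    fit_a = fit_nlmm(dataset, region,
                     StructuralModelSpec(function,
                                         main_fit.spec.random_effects,
                                         None), seed)
    out["no_covariates"] = {
        "estimates": fit_a.structural_estimates(),
        "delta": {p: fit_a.estimate(p) - main_fit.estimate(p)
                  for p in PARAM_NAMES[function]},
        "bic": fit_a.bic,
    }

    # (b) eTIV-adjusted smooth model
    if "etiv" in df.columns and df["etiv"].notna().all():
        spec_b = dataclasses.replace(config.smooth, extra_covariates=("etiv",))
        gamm_b = fit_gamm(dataset, region, spec_b)
        base_gamm = fit_gamm(dataset, region, config.smooth)
        sex_b = _param_estimate(gamm_b, "sex")
        sex_0 = _param_estimate(base_gamm, "sex")
        out["etiv_adjusted"] = {
            "sex_effect": sex_b, "sex_effect_unadjusted": sex_0,
            "sex_p": _param_p(gamm_b, "sex"),
            "age_by_sex_edf": gamm_b.edf.get("s(age):sex"),
            "age_by_sex_p": float(
                gamm_b.smooth_table.set_index("term").loc["s(age):sex", "p"])
            if "s(age):sex" in gamm_b.edf else None,
        }
    else:
        out["notes"].append("etiv arm skipped: no etiv column")

    # (c) scanner-software arm
    if "software" in df.columns:
        spec_c = dataclasses.replace(config.smooth,
                                     extra_covariates=("software",))
        gamm_c = fit_gamm(dataset, region, spec_c)
        cmap = CovariateMap(function, [(scalar, "software", 0.0)])
        fit_c = fit_nlmm(dataset, region,
                         StructuralModelSpec(function,
                                             main_fit.spec.random_effects,
                                             cmap), seed)
        lbl = f"software({scalar})"
        out["software"] = {
            "nlmm_software_coef": fit_c.estimate(lbl),
            "nlmm_software_p": fit_c.wald_p.get(lbl),
            "scalar_estimate": fit_c.estimate(scalar),
            "scalar_delta": fit_c.estimate(scalar) - main_fit.estimate(scalar),
            "gamm_age_edf": gamm_c.edf.get("s(age)"),
        }
    else:
        out["notes"].append("software arm skipped: no software column")
    return out


def _param_estimate(gamm_fit, term):
    t = gamm_fit.parametric.set_index("term")
    return float(t.loc[term, "estimate"]) if term in t.index else None


def _param_p(gamm_fit, term):
    t = gamm_fit.parametric.set_index("term")
    return float(t.loc[term, "p"]) if term in t.index else None


# -- the per-region pipeline ------------------------------------------------

def run_region_analysis(dataset: LongitudinalDataset, region: str,
                        config: PipelineConfig | None = None,
                        seed: int = 0) -> RegionReport:
    """Full per-region analysis; see module docstring for the stages."""
    config = config or PipelineConfig()
    try:
        df = dataset.region_frame(region)
    except KeyError as exc:
        raise RuntimeError(f"[ingestion] {exc}") from exc

    # rescale large global volumes before structural fitting
    work = dataset
    if region in RESCALED_REGIONS and \
            dataset.metadata.get("rescale", {}).get(region, 1) == 1:
        work = rescale_volumes(dataset, [region], config.rescale_divisor)

    try:
        gamm = fit_gamm(work, region, config.smooth)
        shape = classify_shape(gamm)
    except Exception as exc:
        raise RuntimeError(f"[gamm] {exc}") from exc

    has_euler = "euler" in df.columns and df["euler"].notna().all()
    fits = {}
    for function in config.candidate_functions:
        if config.use_covariates:
            entries = [(p, c) for p, c in PAPER_COVARIATES[function]
                       if c != "euler" or has_euler]
            if config.stepwise:
                trace = stepwise_covariates(work, region, function,
                                            entries, seed)
                cmap = trace.final_map
            else:
                cmap = _as_map(function, entries)
        else:
            cmap = None
        spec = StructuralModelSpec(function, None, cmap)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits[function] = fit_nlmm(work, region, spec, seed)
        except Exception as exc:
            raise RuntimeError(f"[nlmm:{function}] {exc}") from exc

    selected, criteria, note = select_structural_model(fits)
    if shape.classification != "nonlinear":
        note += ("; shape call was not nonlinear — structural fits are "
                 "reported for comparison regardless")
    best = fits[selected]

    individual = individual_estimates(best)
    summary = summarize_individual_differences(individual)
    diagnostics = predicted_vs_observed(best, individual)
    age_range = (float(df["age"].min()), float(df["age"].max()))
    scalar_is_age = DERIVED_SCALAR[selected] == "inflection"
    oor = (flag_out_of_range(individual, age_range) if scalar_is_age
           else pd.DataFrame(columns=["subject_id", "sex", "n_obs", "scalar"]))

    gates = {}
    for lbl, cv in zip(best.param_labels, best.cv_percent):
        gates[lbl] = {"cv_percent": float(cv),
                      "precise": bool(np.isfinite(cv) and cv < 20.0)}

    if selected == "logistic":
        # baseline level = the asymptote the curve starts from in childhood
        change = "hill"
        baseline = "a_upper" if best.estimate("hill") < 0 else "a_lower"
    else:
        baseline, change = "a", "b"
    r, dof, p = correlate_baseline_change(individual, baseline, change)
    correlations = {"baseline_param": baseline, "change_param": change,
                    "r": r, "df": dof, "p": p}

    sens = None
    if config.run_sensitivity:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sens = sensitivity_suite(work, region, best, config, seed)

    return RegionReport(
        region=region, shape=shape,
        gamm_parametric=gamm.parametric, gamm_smooths=gamm.smooth_table,
        criteria=criteria, selected_function=selected, selection_note=note,
        population=best, individual=individual, individual_summary=summary,
        cv_gates=gates, out_of_range=oor, diagnostics=diagnostics,
        correlations=correlations, sensitivity=sens,
        provenance={
            "region": region, "seed": seed,
            "n_obs": int(len(df)),
            "n_subjects": int(df["subject_id"].nunique()),
            "rescaled": work.metadata.get("rescale", {}).get(region, 1),
            "stages": ["gamm", "classify_shape", "fit_nlmm x candidates",
                       "select_structural_model", "individual_estimates",
                       "summaries", "correlations"]
            + (["sensitivity_suite"] if sens else []),
        },
    )
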