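"""Synthetic accelerated-longitudinal cohorts with known ground truth.

The real HUBU cohort (N = 90, up to 12 MRI waves between ages 7.6 and 21.6)
is confidential, so every pipeline stage is exercised on simulated twins of
its design: staggered baseline ages 7.60-12.90, six-month visit intervals
for the first ten waves, one year to wave 11 and three years to wave 12,
roughly 31% of follow-up visits missing, and a 53:37 female:male split.

Generating growth models are built from the published group-level estimates
(one preset per region), with additive Gaussian random effects on the
structural parameters and additive Gaussian residual noise.  The published
tables give no within-cohort variance components, so the preset defaults
are stated conventions: between-subject SD = 5% of |parameter| and residual
SD = 2% of the trajectory midpoint.  Ground truth is returned alongside the
dataset so recovery can be measured exactly.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import LongitudinalDataset
from .structural_models import (
    PARAM_NAMES,
    CovariateMap,
    eval_function,
)

__all__ = [
    "DesignConfig",
    "GenerativeModel",
    "PRESET_NAMES",
    "preset",
    "sample_design",
    "simulate_cohort",
]

#: Canonical 12-wave visit offsets (years from baseline).
WAVE_OFFSETS = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.5, 8.5)

#: Number of scanner-software epochs across the study window.
N_SOFTWARE_EPOCHS = 5


@dataclasses.dataclass
class DesignConfig:
    """Accelerated-longitudinal visit schedule configuration."""

    n_subjects: int = 90
    baseline_age_range: tuple[float, float] = (7.60, 12.90)
    wave_offsets: tuple[float, ...] = WAVE_OFFSETS
    visit_missing_prob: float = 0.31
    timing_jitter_sd: float = 0.05
    female_fraction: float = 53 / 90
    seed: int = 0

    def __post_init__(self):
        offs = np.asarray(self.wave_offsets, dtype=float)
        if offs[0] != 0 or np.any(np.diff(offs) <= 0):
            raise ValueError("wave_offsets must start at 0 and strictly increase")
        if not 0 <= self.visit_missing_prob < 1:
            raise ValueError("visit_missing_prob must be in [0, 1)")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must be in [0, 1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclasses.dataclass
class GenerativeModel:
    """Ground-truth growth model for one region.

    ``population_params`` are on the analysis scale (global volumes are the
    /100 scale used for reporting).  ``sex_effects`` are additive shifts for
    males (female reference).  ``motion_effect`` is the coefficient of the
    per-visit mean Euler number on the slope-like parameter (``hill`` or
    ``b``).  Random effects are additive Gaussian with diagonal covariance.
    """

    function: str
    population_params: dict[str, float]
    sex_effects: dict[str, float] = dataclasses.field(default_factory=dict)
    motion_effect: float = 0.0
    between_subject_sd: dict[str, float] = dataclasses.field(default_factory=dict)
    residual_sd: float = 1.0
    scale_divisor: float = 1.0  # divisor already applied to the volume scale
    region: str = "cortical_gm"

    def __post_init__(self):
        names = PARAM_NAMES.get(self.function)
        if names is None:
            raise ValueError(f"unknown function {self.function!r}")
        if set(self.population_params) != set(names):
            raise ValueError(
                f"population_params must have keys {names}, "
                f"got {tuple(self.population_params)}")
        if not self.residual_sd > 0:
            raise ValueError("residual_sd must be > 0")
        if any(sd < 0 for sd in self.between_subject_sd.values()):
            raise ValueError("between_subject_sd must be nonnegative")

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.function]

    @property
    def slope_like(self) -> str:
        """Parameter the motion covariate acts on."""
        return "hill" if self.function == "logistic" else "b"

    def pop_vector(self) -> np.ndarray:
        return np.array([self.population_params[p] for p in self.param_names])

    def sd_vector(self) -> np.ndarray:
        return np.array([self.between_subject_sd.get(p, 0.0)
                         for p in self.param_names])

    def sex_vector(self) -> np.ndarray:
        return np.array([self.sex_effects.get(p, 0.0) for p in self.param_names])

    def covariate_map(self) -> CovariateMap:
        """The generating covariate structure as a fit-ready map."""
        entries = [(p, "sex", c) for p, c in self.sex_effects.items() if c != 0]
        if self.motion_effect:
            entries.append((self.slope_like, "euler", self.motion_effect))
        return CovariateMap(self.function, entries)


# -- published group-level estimates as generating presets ------------------

# (a_lower, a_upper, inflection, hill) + sex shifts + motion-on-hill,
# global volumes on the /100 scale.
_LOGISTIC_PRESETS = {
    "cortical_gm": dict(
        params=dict(a_lower=5089.72, a_upper=6105.41, inflection=14.52, hill=-5.94),
        sex=dict(a_lower=-232.79, a_upper=488.24, inflection=4.92, hill=2.10),
        motion=0.01, divisor=100.0),
    "white_matter": dict(
        params=dict(a_lower=3736.34, a_upper=4555.92, inflection=13.91, hill=3.89),
        sex=dict(a_lower=289.28, a_upper=544.69, inflection=-1.64, hill=0.17),
        motion=0.003, divisor=100.0),
    "pallidum": dict(
        params=dict(a_lower=1741.55, a_upper=2154.30, inflection=10.99, hill=5.17),
        sex=dict(a_lower=192.86, a_upper=230.59, inflection=1.61, hill=1.74),
        motion=0.0016, divisor=1.0),
    "accumbens": dict(
        params=dict(a_lower=435.33, a_upper=674.27, inflection=11.44, hill=-0.43),
        sex=dict(a_lower=133.73, a_upper=44.17, inflection=-2.90, hill=-0.81),
        motion=0.01, divisor=1.0),
}

# (intercept a, slope b) + sex shifts; motion was not part of the published
# linear covariate structure.
_LINEAR_PRESETS = {
    "hippocampus": dict(params=dict(a=4116.00, b=6.50), sex=dict(a=58.60, b=13.40)),
    "amygdala": dict(params=dict(a=1639.66, b=6.44), sex=dict(a=115.55, b=5.32)),
    "caudate": dict(params=dict(a=4673.60, b=-31.00), sex=dict(a=45.90, b=14.40)),
    "putamen": dict(params=dict(a=6185.50, b=-45.70), sex=dict(a=317.50, b=16.30)),
    "thalamus": dict(params=dict(a=8095.50, b=-24.40), sex=dict(a=530.70, b=17.10)),
}

PRESET_NAMES = tuple(sorted(_LOGISTIC_PRESETS) + sorted(_LINEAR_PRESETS))

_AGE_SPAN = (7.6, 21.6)


def preset(name: str, covariates: bool = True,
           between_subject_frac: float = 0.05,
           residual_frac: float = 0.02) -> GenerativeModel:
    """Generating model for a named region, built from published estimates.

    Parameters
    ----------
    name
        Region preset name (see :data:`PRESET_NAMES`).
    covariates
        When ``False``, sex and motion effects are zeroed so the generating
        population matches a covariate-free fit exactly.
    between_subject_frac
        Between-subject SD as a fraction of each |parameter| (default 5%).
    residual_frac
        Residual SD as a fraction of the trajectory midpoint: the asymptote
        midpoint for the logistic, the fitted-line midrange over the study
        ages for linear/logarithmic (default 2%).
    """
    if name in _LOGISTIC_PRESETS:
        src, function = _LOGISTIC_PRESETS[name], "logistic"
    elif name in _LINEAR_PRESETS:
        src, function = _LINEAR_PRESETS[name], "linear"
    else:
        raise KeyError(
            f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}")
    params = dict(src["params"])
    if function == "logistic":
        midpoint = 0.5 * (params["a_lower"] + params["a_upper"])
    else:
        lo = params["a"] + params["b"] * _AGE_SPAN[0]
        hi = params["a"] + params["b"] * _AGE_SPAN[1]
        midpoint = 0.5 * (lo + hi)
    return GenerativeModel(
        function=function,
        population_params=params,
        sex_effects=dict(src["sex"]) if covariates else {},
        motion_effect=src.get("motion", 0.0) if covariates else 0.0,
        between_subject_sd={p: between_subject_frac * abs(v)
                            for p, v in params.items()},
        residual_sd=residual_frac * abs(midpoint),
        scale_divisor=src.get("divisor", 1.0),
        region=name,
    )


# -- design sampling --------------------------------------------------------

def sample_design(config: DesignConfig,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample a per-subject visit schedule.

    Returns a long frame with one row per retained visit: ``subject_id,
    wave, age, sex, euler, software, baseline_age``.  Baseline ages are
    uniform on the configured range; visit ages add the canonical wave
    offsets plus small Gaussian timing jitter; each follow-up visit (waves
    2-12) is independently dropped with ``visit_missing_prob`` — the
    baseline visit is never dropped, so every simulated subject exists.
    Euler numbers are Normal(-150, 80) truncated at 0; software epochs are
    assigned by calendar position (years since study start) cut into
    five ordinal epochs.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    offsets = np.asarray(config.wave_offsets, dtype=float)
    n_waves = len(offsets)

    baseline = rng.uniform(*config.baseline_age_range, size=n)
    n_female = int(round(config.female_fraction * n))
    sex = np.array(["female"] * n_female + ["male"] * (n - n_female))
    rng.shuffle(sex)

    jitter = rng.normal(0.0, config.timing_jitter_sd, size=(n, n_waves))
    jitter[:, 0] = 0.0  # baseline age is the enrollment age itself
    ages = baseline[:, None] + offsets[None, :] + jitter

    keep = rng.uniform(size=(n, n_waves)) >= config.visit_missing_prob
    keep[:, 0] = True  # baseline never dropped

    # visit-quality proxy: mean Euler number, truncated-normal <= 0
    a = (-np.inf - (-150.0)) / 80.0, (0.0 - (-150.0)) / 80.0
    euler = stats.truncnorm.rvs(a[0], a[1], loc=-150.0, scale=80.0,
                                size=(n, n_waves), random_state=rng)

    calendar = ages - baseline[:, None]  # years since each subject's baseline
    edges = np.linspace(0.0, offsets[-1] + 1e-9, N_SOFTWARE_EPOCHS + 1)
    epoch = np.clip(np.searchsorted(edges, calendar, side="right") - 1,
                    0, N_SOFTWARE_EPOCHS - 1)

    rows = []
    width = len(str(n))
    for i in range(n):
        sid = f"S{i + 1:0{width}d}"
        for w in range(n_waves):
            if not keep[i, w]:
                continue
            rows.append((sid, w + 1, ages[i, w], sex[i], euler[i, w],
                         f"v{epoch[i, w] + 1}", baseline[i]))
    return pd.DataFrame(
        rows, columns=["subject_id", "wave", "age", "sex", "euler",
                       "software", "baseline_age"])


# -- cohort simulation ------------------------------------------------------

def simulate_cohort(design: DesignConfig, model: GenerativeModel,
                    region: str | None = None, seed: int | None = None,
                    etiv: bool = False,
                    ) -> tuple[LongitudinalDataset, pd.DataFrame]:
    """Simulate one region's cohort; returns (dataset, truth table).

    Subject parameters are
    ``phi_i = population + sex_effects * 1[male] + eta_i`` with
    ``eta_i ~ N(0, diag(between_subject_sd^2))``; the motion effect is added
    per visit on the slope-like parameter (``motion_effect * euler_ij``).
    Observed volume is the mean function plus N(0, residual_sd^2) noise.
    Logistic draws with nonpositive inflection are resampled (with a
    warning).  Fully reproducible under ``seed`` (defaults to the design's).
    """
    region = region or model.region
    rng = np.random.default_rng(design.seed if seed is None else seed)
    schedule = sample_design(design, rng)

    names = model.param_names
    pop = model.pop_vector()
    sds = model.sd_vector()
    sexv = model.sex_vector()

    subjects = schedule.drop_duplicates("subject_id")[["subject_id", "sex"]]
    m = len(subjects)
    male = (subjects["sex"].to_numpy() == "male").astype(float)

    eta = rng.normal(0.0, 1.0, size=(m, len(names))) * sds[None, :]
    phi = pop[None, :] + sexv[None, :] * male[:, None] + eta

    if model.function == "logistic":
        idx_infl = names.index("inflection")
        n_resampled = 0
        bad = phi[:, idx_infl] <= 0
        while bad.any():
            n_resampled += int(bad.sum())
            redraws = rng.normal(0.0, sds[idx_infl], size=int(bad.sum()))
            phi[bad, idx_infl] = (pop[idx_infl]
                                  + sexv[idx_infl] * male[bad] + redraws)
            bad = phi[:, idx_infl] <= 0
        if n_resampled:
            warnings.warn(
                f"resampled {n_resampled} nonpositive inflection draw(s)",
                stacklevel=2)

    sid_to_row = {s: i for i, s in enumerate(subjects["subject_id"])}
    rows = schedule["subject_id"].map(sid_to_row).to_numpy()
    phi_obs = phi[rows].copy()
    if model.motion_effect:
        k = names.index(model.slope_like)
        phi_obs[:, k] += model.motion_effect * schedule["euler"].to_numpy()

    ages = schedule["age"].to_numpy()
    mean = np.empty(len(schedule))
    for i in range(len(schedule)):  # parameters vary per row under motion
        mean[i] = eval_function(model.function, phi_obs[i], ages[i])
    volume = mean + rng.normal(0.0, model.residual_sd, size=len(schedule))
    volume = np.maximum(volume, 1e-9)  # volumes are positive by contract

    frame = schedule[["subject_id", "wave", "age", "sex", "euler",
                      "software"]].copy()
    frame["region"] = region
    frame["volume"] = volume
    if etiv:
        # crude head-size proxy: sex-shifted constant per subject (litres *
        # 1e6 mm^3 scale), used only by the eTIV sensitivity arm
        base = 1.45e6 + 1.0e5 * male + rng.normal(0, 5e4, size=m)
        frame["etiv"] = base[rows]
    frame = frame[["subject_id", "wave", "age", "sex", "region", "volume",
                   "euler", "software"] + (["etiv"] if etiv else [])]

    truth = subjects.reset_index(drop=True).copy()
    for j, p in enumerate(names):
        truth[p] = phi[:, j]
    truth["n_visits"] = (schedule.groupby("subject_id").size()
                         .reindex(truth["subject_id"]).to_numpy())

    metadata = {
        "study": "synthetic-hubu-like",
        "units": "mm^3",
        "rescale": ({region: model.scale_divisor}
                    if model.scale_divisor != 1 else {}),
        "generating_function": model.function,
    }
    return LongitudinalDataset(frame, metadata=metadata), truth
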