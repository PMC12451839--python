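"""The three structural growth functions and the parameter-covariate mapping.

Volumetric development between late childhood and late adolescence is
modelled with one of three candidate mean functions of age ``x``:

* four-parameter logistic
  ``y = a_lower + (a_upper - a_lower) / (1 + (x / inflection)**(-hill))`` —
  an S-shaped trajectory whose *inflection* parameter is the age at which the
  curve crosses the midpoint of its asymptotes (the paper-style index of
  maturational timing),
* logarithmic ``y = a + b * ln(x)`` — decelerating change, and
* linear ``y = a + b * x`` — constant rate of change.

Covariates (sex with female as the reference level, in-scanner motion via
the mean Euler number, scanner-software epoch) enter additively on
individual structural parameters through a :class:`CovariateMap`.

A note on identifiability: swapping ``a_lower`` and ``a_upper`` while
negating ``hill`` leaves the logistic curve unchanged.  Direction of change
is therefore carried by the sign of ``hill`` (``hill > 0`` rises toward
``a_upper``; ``hill < 0`` falls toward ``a_lower``) and no asymptote
ordering is imposed.  The fitting engine resolves the symmetry by
data-driven initialization.

A second caveat worth documenting: ``inflection`` is the age at which the
curve crosses the asymptote midpoint.  For this power-law-in-x
parameterization the literal maximizer of ``|dy/dx|`` on the linear age
scale is slightly offset from that midpoint age; the midpoint parameter is
what is estimated and reported.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LogisticParams",
    "LogarithmicParams",
    "LinearParams",
    "CovariateEntry",
    "CovariateMap",
    "PARAM_NAMES",
    "DERIVED_SCALAR",
    "eval_logistic",
    "eval_logarithmic",
    "eval_linear",
    "eval_function",
    "individual_params",
]

#: Structural parameter names per function family, in canonical order.
PARAM_NAMES = {
    "logistic": ("a_lower", "a_upper", "inflection", "hill"),
    "logarithmic": ("a", "b"),
    "linear": ("a", "b"),
}

#: The per-subject scalar of scientific interest for each family:
#: maturational timing (logistic) or rate of change (others).
DERIVED_SCALAR = {"logistic": "inflection", "logarithmic": "b", "linear": "b"}


@dataclasses.dataclass(frozen=True)
class LogisticParams:
    a_lower: float
    a_upper: float
    inflection: float
    hill: float

    def __post_init__(self):
        if not self.inflection > 0:
            raise ValueError(f"inflection must be > 0, got {self.inflection}")
        for name in ("a_lower", "a_upper", "inflection", "hill"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.a_lower, self.a_upper, self.inflection, self.hill])


@dataclasses.dataclass(frozen=True)
class LogarithmicParams:
    a: float  # value at x = 1 year; outside the studied range, not interpreted
    b: float  # volume units per log-year

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b])


@dataclasses.dataclass(frozen=True)
class LinearParams:
    a: float  # intercept, volume units
    b: float  # slope, volume units per year

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b])


@dataclasses.dataclass(frozen=True)
class CovariateEntry:
    """One additive covariate effect on one structural parameter."""

    parameter: str
    covariate: str  # column name; "sex" is coded 0=female, 1=male
    coefficient: float | None = None  # None until estimated


class CovariateMap:
    """Collection of (parameter, covariate) entries for one function family.

    The logistic admits at most 8 entries (two covariates times four
    parameters); logarithmic and linear at most 4.  Each (parameter,
    covariate) pair may appear once.  Female is the reference sex level.
    """

    def __init__(self, function: str,
                 entries: Iterable[CovariateEntry | tuple] = ()):
        if function not in PARAM_NAMES:
            raise ValueError(f"unknown function {function!r}")
        self.function = function
        self.entries: list[CovariateEntry] = []
        for e in entries:
            if not isinstance(e, CovariateEntry):
                e = CovariateEntry(*e)
            self.add(e)

    def add(self, entry: CovariateEntry) -> None:
        if entry.parameter not in PARAM_NAMES[self.function]:
            raise ValueError(
                f"{entry.parameter!r} is not a parameter of the "
                f"{self.function} function")
        if any(e.parameter == entry.parameter and e.covariate == entry.covariate
               for e in self.entries):
            raise ValueError(
                f"duplicate covariate entry ({entry.parameter}, {entry.covariate})")
        limit = 8 if self.function == "logistic" else 4
        if len(self.entries) >= limit:
            raise ValueError(
                f"{self.function} model admits at most {limit} covariate entries")
        self.entries.append(entry)

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def labels(self) -> list[str]:
        return [f"{e.covariate}({e.parameter})" for e in self.entries]

    def __repr__(self):
        return f"CovariateMap({self.function}, {self.labels()})"


# -- mean functions ---------------------------------------------------------

def eval_logistic(params, x):
    """Four-parameter logistic trajectory evaluated at age(s) ``x`` (> 0)."""
    if isinstance(params, LogisticParams):
        a_lower, a_upper, inflection, hill = params.as_array()
    else:
        a_lower, a_upper, inflection, hill = params
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("age x must be > 0 for the logistic function")
    # (x / inflection) ** (-hill), computed on the log scale for stability
    t = np.exp(-hill * (np.log(x) - np.log(inflection)))
    return a_lower + (a_upper - a_lower) / (1.0 + t)


def eval_logarithmic(params, x):
    """``a + b ln(x)`` for age(s) ``x`` (> 0); natural log."""
    if isinstance(params, LogarithmicParams):
        a, b = params.as_array()
    else:
        a, b = params
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("age x must be > 0 for the logarithmic function")
    return a + b * np.log(x)


def eval_linear(params, x):
    """``a + b x``."""
    if isinstance(params, LinearParams):
        a, b = params.as_array()
    else:
        a, b = params
    return a + b * np.asarray(x, dtype=float)


_EVAL = {
    "logistic": eval_logistic,
    "logarithmic": eval_logarithmic,
    "linear": eval_linear,
}


def eval_function(function: str, params, x):
    """Dispatch to the named mean function."""
    try:
        return _EVAL[function](params, x)
    except KeyError:
        raise ValueError(f"unknown function {function!r}") from None


def eval_gradient(function: str, params: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the mean function w.r.t. its structural params.

    Returns shape ``(len(x), n_params)``, columns in canonical order.  Used
    by the fitting engine's Gauss-Newton inner step.
    """
    x = np.asarray(x, dtype=float)
    if function == "linear":
        return np.column_stack([np.ones_like(x), x])
    if function == "logarithmic":
        return np.column_stack([np.ones_like(x), np.log(x)])
    if function == "logistic":
        a_lower, a_upper, inflection, hill = params
        logratio = np.log(x) - np.log(inflection)
        t = np.exp(-hill * logratio)
        u = 1.0 / (1.0 + t)
        span = a_upper - a_lower
        d_alow = 1.0 - u
        d_aup = u
        d_infl = -span * hill * t * u * u / inflection
        d_hill = span * t * logratio * u * u
        return np.column_stack([d_alow, d_aup, d_infl, d_hill])
    raise ValueError(f"unknown function {function!r}")


# -- covariate application --------------------------------------------------

def individual_params(population: Sequence[float],
                      covariates: dict,
                      cov_map: CovariateMap | None,
                      random_effect: Sequence[float] | None = None,
                      subject: str | None = None) -> np.ndarray:
    """Subject-specific parameter vector.

    ``phi_i = population + sum(coefficient * covariate value) + random_effect``
    applied per mapped parameter.  A female, zero-motion subject with zero
    random effect gets the population vector unchanged (female is the
    reference level; sex is coded 0 for female, 1 for male).

    ``covariates`` maps covariate name to its numeric value for this subject
    (e.g. ``{"sex": 1, "euler": -200.0}``).
    """
    names = PARAM_NAMES[cov_map.function] if cov_map is not None else None
    phi = np.array(population, dtype=float)
    if cov_map is not None:
        for entry in cov_map:
            if entry.covariate not in covariates:
                who = f" for subject {subject!r}" if subject else ""
                raise KeyError(
                    f"missing covariate {entry.covariate!r}{who} "
                    f"(mapped to parameter {entry.parameter!r})")
            if entry.coefficient is None:
                raise ValueError(
                    f"covariate entry {entry.covariate}({entry.parameter}) "
                    "has no coefficient")
            idx = names.index(entry.parameter)
            phi[idx] += entry.coefficient * float(covariates[entry.covariate])
    if random_effect is not None:
        phi = phi + np.asarray(random_effect, dtype=float)
    return phi
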