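"""Model parameters: rate/probability algebra and sampling-distribution fits.

All base-case inputs of the cost-utility model live in :class:`ParameterSet`:
quarterly event probabilities and treatment hazard ratios estimated in the
DAPA-HF trial, EQ-5D-anchored utilities, and 2023-US$ unit costs from Brazilian
administrative reimbursement databases.  The module also provides the standard
rate/probability conversions for a 3-month cycle and the method-of-moments
distribution fits (beta for probabilities and utilities, gamma for costs,
log-normal for hazard ratios) used by the probabilistic sensitivity analysis.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "HazardRatio",
    "DistributionSpec",
    "ParameterSet",
    "rate_to_prob",
    "prob_to_rate",
    "apply_hazard_ratio",
    "fit_beta",
    "fit_gamma",
    "fit_lognormal_hr",
    "default_ranges",
    "fallback_range",
    "fit_all_distributions",
    "distribution_table",
    "load_config",
]

#: Half-width of a 95% normal interval in standard deviations.
_Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# rate <-> probability algebra
# ---------------------------------------------------------------------------

def rate_to_prob(rate: float, t: float) -> float:
    """Convert an event rate (events per person-year) to the probability of at
    least one event within ``t`` years, assuming a constant (exponential) rate:
    ``p = 1 - exp(-rate * t)``.

    >>> round(rate_to_prob(0.098, 0.25), 3)
    0.024
    """
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    if t <= 0:
        raise ValueError(f"time interval must be positive, got {t}")
    return -math.expm1(-rate * t)


def prob_to_rate(p: float, t: float) -> float:
    """Inverse of :func:`rate_to_prob`: the constant rate implied by event
    probability ``p`` over ``t`` years, ``r = -ln(1 - p) / t``."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    if t <= 0:
        raise ValueError(f"time interval must be positive, got {t}")
    return -math.log1p(-p) / t


def apply_hazard_ratio(p: float, hr: float, t: float = 0.25) -> float:
    """Scale a cycle probability by a hazard ratio on the rate scale.

    The probability is converted to a rate, multiplied by ``hr``, and converted
    back, which collapses to ``1 - (1 - p)**hr``.  ``t`` cancels and is accepted
    only for signature symmetry with the conversion helpers.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    if hr < 0:
        raise ValueError(f"hazard ratio must be non-negative, got {hr}")
    return -math.expm1(hr * math.log1p(-p))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HazardRatio:
    """Treatment hazard ratio with its 95% confidence interval."""

    value: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low > 0 and self.ci_high > 0 and self.value > 0):
            raise ValueError("hazard ratio and CI bounds must be positive")
        if not self.ci_low <= self.value <= self.ci_high:
            raise ValueError(
                f"hazard ratio {self.value} outside its CI "
                f"[{self.ci_low}, {self.ci_high}]"
            )


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one model parameter.

    ``family`` is one of ``beta``, ``gamma``, ``lognormal`` or ``degenerate``.
    ``param1``/``param2`` are (alpha, beta) for beta, (shape, scale) for gamma,
    (mu, sigma) of the underlying normal for lognormal, and (value, 0) for a
    degenerate point mass.  ``negate`` marks disutilities that are fitted on
    their absolute value and sign-flipped at sampling time.
    """

    family: str
    param1: float
    param2: float
    source_mean: float
    low: float
    high: float
    negate: bool = False

    def mean(self) -> float:
        """Analytic mean (median for lognormal) of the fitted distribution,
        on the original (possibly negative) scale."""
        if self.family == "beta":
            m = self.param1 / (self.param1 + self.param2)
        elif self.family == "gamma":
            m = self.param1 * self.param2
        elif self.family == "lognormal":
            m = math.exp(self.param1)  # median; the PSA anchors HRs on it
        elif self.family == "degenerate":
            m = self.param1
        else:  # pragma: no cover - guarded at construction
            raise ValueError(f"unknown family {self.family!r}")
        return -m if self.negate else m

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the fitted distribution (scalar or array)."""
        if self.family == "beta":
            x = rng.beta(self.param1, self.param2, size=size)
        elif self.family == "gamma":
            x = rng.gamma(self.param1, self.param2, size=size)
        elif self.family == "lognormal":
            x = rng.lognormal(self.param1, self.param2, size=size)
        else:
            x = self.param1 if size is None else np.full(size, self.param1)
        return -x if self.negate else x


def _degenerate(value: float, low: float, high: float, negate: bool = False) -> DistributionSpec:
    return DistributionSpec("degenerate", value, 0.0, value, low, high, negate)


def fit_beta(mean: float, low: float, high: float, *, negate: bool = False) -> DistributionSpec:
    """Method-of-moments beta fit from a mean and a 95% range.

    The standard deviation is taken as ``(high - low) / (2 * 1.96)``.  A
    zero-width range yields a degenerate point mass.  If the implied variance
    is infeasible for a beta distribution (``var >= mean * (1 - mean)``) the
    fit falls back to a degenerate distribution with a logged warning rather
    than failing.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must lie strictly in (0, 1), got {mean}")
    if not (0.0 <= low <= high <= 1.0):
        raise ValueError(f"invalid beta range [{low}, {high}]")
    if high == low:
        return _degenerate(mean, low, high, negate)
    sd = (high - low) / (2.0 * _Z95)
    var = sd * sd
    if var >= mean * (1.0 - mean):
        logger.warning(
            "beta moments infeasible for mean=%g, range=(%g, %g); "
            "falling back to a degenerate distribution", mean, low, high,
        )
        warnings.warn(
            f"infeasible beta moments (mean={mean}, range=({low}, {high})); "
            "using a degenerate distribution",
            RuntimeWarning,
            stacklevel=2,
        )
        return _degenerate(mean, low, high, negate)
    nu = mean * (1.0 - mean) / var - 1.0
    return DistributionSpec("beta", mean * nu, (1.0 - mean) * nu, mean, low, high, negate)


def fit_gamma(mean: float, low: float, high: float) -> DistributionSpec:
    """Method-of-moments gamma fit from a mean and a 95% range
    (sd = range width / 3.92); zero-width ranges degenerate."""
    if mean <= 0:
        raise ValueError(f"gamma mean must be positive, got {mean}")
    if not (0.0 <= low <= high):
        raise ValueError(f"invalid gamma range [{low}, {high}]")
    if high == low:
        return _degenerate(mean, low, high)
    sd = (high - low) / (2.0 * _Z95)
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return DistributionSpec("gamma", shape, scale, mean, low, high)


def fit_lognormal_hr(hr: HazardRatio) -> DistributionSpec:
    """Log-normal fit for a hazard ratio: the log of the point estimate is the
    location and the log-CI width divided by 3.92 the scale, so the fitted
    median equals the point estimate."""
    if hr.ci_high == hr.ci_low:
        return _degenerate(hr.value, hr.ci_low, hr.ci_high)
    sigma = (math.log(hr.ci_high) - math.log(hr.ci_low)) / (2.0 * _Z95)
    return DistributionSpec(
        "lognormal", math.log(hr.value), sigma, hr.value, hr.ci_low, hr.ci_high
    )


# ---------------------------------------------------------------------------
# the full parameter set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSet:
    """Every model input, defaulting to the base case.

    Probabilities are per 3-month cycle; costs are 2023 US$ per cycle
    (medication) or per event (hospitalization, urgent visit); the utility is
    on the 0-1 EQ-5D scale with one-off event disutilities.
    """

    # -- quarterly event probabilities (standard-care arm) ------------------
    p_urgent: float = 0.002          # urgent HF care visit, per cycle
    p_hosp: float = 0.024            # HF hospitalization, cycle 1 (escalates with age)
    p_death_cycle1: float = 0.021    # all-cause death at age 66 (calibration anchor)
    p_inhosp_death: float = 0.09     # death during a HF admission
    p_readmit: float = 0.246         # readmission in the cycle after discharge

    # -- dapagliflozin treatment effects (hazard ratios) --------------------
    hr_death: HazardRatio = HazardRatio(0.83, 0.71, 0.97)
    hr_urgent: HazardRatio = HazardRatio(0.43, 0.20, 0.90)
    hr_hosp: HazardRatio = HazardRatio(0.70, 0.59, 0.83)

    # -- quality of life ----------------------------------------------------
    u_base: float = 0.78             # ongoing-HF utility at cycle 1
    du_hosp: float = -0.100          # one-off disutility per (re)admission
    du_urgent: float = -0.036        # one-off disutility per urgent visit
    utility_decrement_per_cycle: float = 0.00174  # relative decline per cycle

    # -- costs, 2023 US$ ----------------------------------------------------
    c_standard: float = 82.71        # standard therapy + monitoring, per cycle
    c_dapa: float = 74.97            # dapagliflozin add-on, per cycle
    c_urgent: float = 18.53          # per urgent visit
    c_hosp: float = 611.09           # per (re)admission

    # -- model settings -----------------------------------------------------
    discount_rate: float = 0.05      # annual, applied to costs and effects
    cohort_size: int = 1000
    start_age: float = 66.0
    cycle_length: float = 0.25       # years
    mortality_rate_ratio: float = 4.6   # HFrEF vs general-population mortality
    mortality_scale: float = 1.0     # extra multiplier on the background rate
    hosp_escalation: float = 1.16    # annual multiplier on the admission rate
    wtp: float = 8000.0              # cost-effectiveness threshold, US$/QALY
    max_age: float = 110.0
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        for name in ("p_urgent", "p_hosp", "p_death_cycle1",
                     "p_inhosp_death", "p_readmit"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.u_base <= 1.0:
            raise ValueError(f"u_base={self.u_base} outside [0, 1]")
        if self.du_hosp > 0 or self.du_urgent > 0:
            raise ValueError("disutilities must be <= 0")
        for name in ("c_standard", "c_dapa", "c_urgent", "c_hosp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be >= 0")
        if self.cohort_size < 1:
            raise ValueError("cohort size must be >= 1")
        if self.hosp_escalation < 1:
            raise ValueError("hospitalization escalation factor must be >= 1")
        if self.mortality_rate_ratio <= 0 or self.mortality_scale <= 0:
            raise ValueError("mortality multipliers must be positive")

    def with_overrides(self, **kwargs) -> "ParameterSet":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


# Table-driven description of every parameter varied in the sensitivity
# analyses: (field, distribution family, stated 95% range or None).
_SENSITIVITY_ROWS: tuple[tuple[str, str, tuple[float, float] | None], ...] = (
    ("p_urgent", "beta", (0.001, 0.003)),
    ("p_hosp", "beta", (0.022, 0.026)),
    ("p_death_cycle1", "beta", (0.019, 0.023)),
    ("p_inhosp_death", "beta", (0.08, 0.10)),
    ("p_readmit", "beta", (0.209, 0.287)),
    ("hr_death", "lognormal", None),
    ("hr_urgent", "lognormal", None),
    ("hr_hosp", "lognormal", None),
    ("u_base", "beta", (0.66, 0.89)),
    ("du_hosp", "beta", (-0.130, -0.080)),
    ("du_urgent", "beta", (-0.0396, -0.0324)),
    ("c_standard", "gamma", (66.17, 99.25)),
    ("c_dapa", "gamma", (65.72, 82.22)),
    ("c_urgent", "gamma", (14.82, 22.24)),
    ("c_hosp", "gamma", (488.80, 733.20)),
)

#: Names of the varied parameters, in the canonical sampling order.
SENSITIVITY_PARAMETERS: tuple[str, ...] = tuple(r[0] for r in _SENSITIVITY_ROWS)


def fallback_range(value: float, family: str) -> tuple[float, float]:
    """Variation bounds for a parameter without a stated range: ±10% for
    probabilities/utilities (beta), ±20% for costs (gamma)."""
    frac = 0.2 if family == "gamma" else 0.1
    lo, hi = value * (1 - frac), value * (1 + frac)
    return (hi, lo) if lo > hi else (lo, hi)


def default_ranges(params: ParameterSet) -> dict[str, tuple[float, float]]:
    """Low/high variation bounds for every parameter in the sensitivity set.

    A stated 95% range takes precedence; otherwise probabilities and utilities
    vary by ±10% and costs by ±20% around the base value (see
    :func:`fallback_range`).  Hazard ratios use their confidence intervals.
    """
    out: dict[str, tuple[float, float]] = {}
    for name, family, rng in _SENSITIVITY_ROWS:
        if family == "lognormal":
            hr: HazardRatio = getattr(params, name)
            out[name] = (hr.ci_low, hr.ci_high)
            continue
        if rng is not None:
            lo, hi = rng
            if lo > hi:  # stated the natural way for negative disutilities
                lo, hi = hi, lo
        else:
            lo, hi = fallback_range(getattr(params, name), family)
        out[name] = (lo, hi)
    return out


def fit_all_distributions(params: ParameterSet) -> dict[str, DistributionSpec]:
    """Fit the PSA sampling distribution of every varied parameter.

    Disutilities are fitted as beta on their absolute value and negated at
    sampling time; hazard ratios are log-normal anchored on the point
    estimate; costs are gamma.  Iteration order is the canonical sampling
    order (:data:`SENSITIVITY_PARAMETERS`).
    """
    ranges = default_ranges(params)
    specs: dict[str, DistributionSpec] = {}
    for name, family, _ in _SENSITIVITY_ROWS:
        lo, hi = ranges[name]
        value = getattr(params, name)
        if family == "lognormal":
            specs[name] = fit_lognormal_hr(value)
        elif family == "gamma":
            specs[name] = fit_gamma(value, lo, hi)
        elif value < 0:
            specs[name] = fit_beta(-value, -hi, -lo, negate=True)
        else:
            specs[name] = fit_beta(value, lo, hi)
    return specs


def distribution_table(specs: Mapping[str, DistributionSpec]) -> pd.DataFrame:
    """Fitted-distribution summary as a DataFrame (exportable to CSV)."""
    rows = [
        {
            "parameter": name,
            "family": s.family,
            "param1": s.param1,
            "param2": s.param2,
            "source_mean": -s.source_mean if s.negate else s.source_mean,
            "low": -s.high if s.negate else s.low,
            "high": -s.low if s.negate else s.high,
        }
        for name, s in specs.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

_CONFIG_SECTIONS: dict[str, tuple[str, ...]] = {
    "probabilities": ("p_urgent", "p_hosp", "p_death_cycle1",
                      "p_inhosp_death", "p_readmit"),
    "hazard_ratios": ("hr_death", "hr_urgent", "hr_hosp"),
    "utilities": ("u_base", "du_hosp", "du_urgent",
                  "utility_decrement_per_cycle"),
    "costs": ("c_standard", "c_dapa", "c_urgent", "c_hosp"),
    "settings": ("discount_rate", "cohort_size", "start_age", "cycle_length",
                 "mortality_rate_ratio", "mortality_scale", "hosp_escalation",
                 "wtp", "max_age", "half_cycle_correction"),
}


def load_config(path: str | Path | None = None) -> ParameterSet:
    """Build a :class:`ParameterSet` from a YAML config file.

    The file has sections ``probabilities``, ``hazard_ratios``, ``utilities``,
    ``costs`` and ``settings``; every key defaults to the base case, so an
    empty (or absent) file reproduces it.  Hazard ratios are given as
    ``{value, ci_low, ci_high}`` mappings.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    overrides: dict = {}
    known = {f.name for f in fields(ParameterSet)}
    for section, keys in _CONFIG_SECTIONS.items():
        block = data.get(section) or {}
        if not isinstance(block, Mapping):
            raise ValueError(f"config section {section!r} must be a mapping")
        for key, value in block.items():
            if key not in keys:
                raise ValueError(f"unknown key {key!r} in config section {section!r}")
            if key.startswith("hr_"):
                value = HazardRatio(**value)
            overrides[key] = value
    unknown_sections = set(data) - set(_CONFIG_SECTIONS)
    if unknown_sections:
        raise ValueError(f"unknown config sections: {sorted(unknown_sections)}")
    assert set(overrides) <= known
    return ParameterSet(**overrides)


def dump_config(params: ParameterSet, path: str | Path) -> None:
    """Write the fully resolved parameter set as a YAML snapshot."""
    out: dict[str, dict] = {}
    for section, keys in _CONFIG_SECTIONS.items():
        out[section] = {}
        for key in keys:
            v = getattr(params, key)
            if isinstance(v, HazardRatio):
                v = {"value": v.value, "ci_low": v.ci_low, "ci_high": v.ci_high}
            out[section][key] = v
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
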