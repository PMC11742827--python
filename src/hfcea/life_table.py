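"""Age-specific background mortality and its HFrEF calibration.

The cohort model needs an all-cause mortality rate at every (fractional) age.
A :class:`LifeTable` supplies it, either loaded from a two-column CSV
(``age,annual_mortality_rate``) or synthesized from a Gompertz law.  HFrEF
excess mortality is introduced through the DEALE device: the trial mortality
rate is expressed as a constant ratio to the age-matched population rate, and
that ratio multiplies the background rate at every age before conversion to
quarterly transition probabilities.

The synthetic table stands in for a national (e.g. census) life table.  Its
default calibration fixes the annual rate at age 66 to 0.01846 per person-year
-- the value that, scaled by the rate ratio 4.6 and converted to a 3-month
probability, gives the model's first-cycle death probability of 0.021 -- with
a Gompertz log-slope of 0.095 per year of age, a typical adult value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import rate_to_prob

__all__ = [
    "GompertzParams",
    "LifeTable",
    "deale_rate_ratio",
    "synthesize_life_table",
    "load_life_table",
    "adjusted_quarterly_death_prob",
]

#: Annual all-cause mortality rate at the reference age that the default
#: synthetic table is calibrated to (per person-year at age 66).
CALIBRATED_RATE_AGE66 = 0.01846

#: Default Gompertz log-slope (per year of age) of the synthetic table.
DEFAULT_GOMPERTZ_SLOPE = 0.095


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz mortality law ``rate(a) = alpha * exp(beta * (a - ref_age))``."""

    alpha: float = CALIBRATED_RATE_AGE66
    beta: float = DEFAULT_GOMPERTZ_SLOPE
    ref_age: float = 66.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("Gompertz alpha must be positive")
        if self.beta < 0:
            raise ValueError("Gompertz beta must be non-negative")

    def rate(self, age: float) -> float:
        return self.alpha * math.exp(self.beta * (age - self.ref_age))


class LifeTable:
    """Annual all-cause mortality rates indexed by exact age in years.

    Rates between integer tabulated ages are linearly interpolated; ages above
    the last row are extrapolated by log-linear (Gompertz) continuation of the
    last two rows.  Ages below the first row are a caller error.
    """

    def __init__(self, ages: np.ndarray, rates: np.ndarray):
        ages = np.asarray(ages, dtype=float)
        rates = np.asarray(rates, dtype=float)
        if ages.ndim != 1 or ages.shape != rates.shape or len(ages) < 2:
            raise ValueError("life table needs matching 1-d age/rate arrays of length >= 2")
        if not np.all(np.diff(ages) > 0):
            bad = int(np.flatnonzero(np.diff(ages) <= 0)[0]) + 1
            raise ValueError(f"ages must be strictly increasing (row {bad})")
        if not np.all(rates > 0):
            bad = int(np.flatnonzero(rates <= 0)[0])
            raise ValueError(f"mortality rates must be positive (row {bad}, age {ages[bad]:g})")
        self.ages = ages
        self.rates = rates
        # slope for log-linear extrapolation beyond the table
        a0, a1 = ages[-2], ages[-1]
        self._tail_slope = (math.log(rates[-1]) - math.log(rates[-2])) / (a1 - a0)

    @property
    def min_age(self) -> float:
        return float(self.ages[0])

    @property
    def max_age(self) -> float:
        return float(self.ages[-1])

    def rate(self, age: float) -> float:
        """Annual mortality rate at an exact (fractional) age."""
        if age < self.min_age:
            raise ValueError(
                f"age {age:g} below the life table's minimum tabulated age "
                f"{self.min_age:g}"
            )
        if age > self.max_age:
            return float(self.rates[-1] * math.exp(self._tail_slope * (age - self.max_age)))
        return float(np.interp(age, self.ages, self.rates))

    def rate_vector(self, ages: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`rate` (same interpolation/extrapolation rules)."""
        ages = np.asarray(ages, dtype=float)
        if np.any(ages < self.min_age):
            raise ValueError("age below the life table's minimum tabulated age")
        out = np.interp(ages, self.ages, self.rates)
        over = ages > self.max_age
        if np.any(over):
            out[over] = self.rates[-1] * np.exp(self._tail_slope * (ages[over] - self.max_age))
        return out

    def life_expectancy(self, age: float, *, max_age: float = 120.0,
                        step: float = 0.25) -> float:
        """Remaining life expectancy from the table alone (no excess
        mortality), by discrete-time survival on a quarterly grid."""
        le = 0.0
        surv = 1.0
        a = age
        while a < max_age and surv > 1e-12:
            surv *= 1.0 - rate_to_prob(self.rate(a), step)
            le += surv * step
            a += step
        return le

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "annual_mortality_rate": self.rates})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def deale_rate_ratio(trial_rate: float, population_rate: float) -> float:
    """Constant mortality rate ratio of a diseased cohort to the age-matched
    population (the DEALE exponential-survival device): trial / population."""
    if trial_rate <= 0:
        raise ValueError("trial mortality rate must be positive")
    if population_rate <= 0:
        raise ValueError("population mortality rate must be positive")
    return trial_rate / population_rate


def synthesize_life_table(params: GompertzParams | None = None,
                          *, min_age: float = 50.0,
                          max_age: float = 110.0) -> LifeTable:
    """Generate a Gompertz life table on integer ages ``min_age..max_age``.

    With the default :class:`GompertzParams` the table reproduces the model's
    calibration anchor: rate(66) = 0.01846 per person-year.
    """
    if params is None:
        params = GompertzParams()
    if max_age < 110:
        raise ValueError("synthetic life tables must extend to at least age 110")
    ages = np.arange(float(min_age), float(max_age) + 1.0)
    rates = params.alpha * np.exp(params.beta * (ages - params.ref_age))
    return LifeTable(ages, rates)


def load_life_table(path: str | Path) -> LifeTable:
    """Read a life table from CSV with header ``age,annual_mortality_rate``."""
    df = pd.read_csv(path)
    missing = {"age", "annual_mortality_rate"} - set(df.columns)
    if missing:
        raise ValueError(
            f"life table {path} is missing required column(s): {sorted(missing)}"
        )
    for col in ("age", "annual_mortality_rate"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise ValueError(
                f"life table {path}: non-numeric {col!r} value at data row {row}"
            )
        df[col] = coerced
    try:
        return LifeTable(df["age"].to_numpy(), df["annual_mortality_rate"].to_numpy())
    except ValueError as err:
        raise ValueError(f"life table {path}: {err}") from err


def adjusted_quarterly_death_prob(table: LifeTable, age: float,
                                  rate_ratio: float, hr: float = 1.0) -> float:
    """Quarterly all-cause death probability for the HFrEF cohort at an age.

    The background rate is scaled by the DEALE ``rate_ratio`` and by the
    treatment hazard ratio (``hr=1`` for standard care), then converted to a
    3-month probability; capped at 1.
    """
    if rate_ratio <= 0:
        raise ValueError("rate ratio must be positive")
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    return min(1.0, rate_to_prob(table.rate(age) * rate_ratio * hr, 0.25))
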