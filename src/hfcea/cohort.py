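"""Three-state quarterly Markov cohort engine.

The cohort starts in STABLE heart failure at a given age and moves between
STABLE, POST-HOSPITALIZATION and DEAD in 3-month cycles.  Within a cycle the
event order is: background all-cause death first (age-specific population
rate scaled by the HFrEF rate ratio and the arm's mortality hazard ratio),
then heart-failure hospitalization for the survivors (with an in-hospital
case-fatality applied to the admitted flow), then urgent care visits as
within-cycle events for the non-hospitalized survivors.  Patients in
POST-HOSPITALIZATION face an elevated readmission probability; a readmission
carries the same cost, disutility and in-hospital fatality as a first
admission and leaves the patient in POST-HOSPITALIZATION, otherwise the
patient returns to STABLE.  DEAD is absorbing.

Costs and QALYs accrue on end-of-cycle occupancy (an optional half-cycle
correction averages start- and end-of-cycle occupancy) and are discounted
at an annual rate compounded per quarter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .life_table import LifeTable, adjusted_quarterly_death_prob
from .parameters import ParameterSet, apply_hazard_ratio, prob_to_rate

__all__ = [
    "ArmSpec",
    "ExtraEvent",
    "CohortTrace",
    "escalate_hosp_prob",
    "cycle_utility",
    "cycle_transition",
    "run_cohort",
]

#: Occupancy below which a lifetime run stops early.
ALIVE_EPSILON = 1e-9

_CONSERVATION_TOL = 1e-12


@dataclass(frozen=True)
class ArmSpec:
    """One treatment strategy: its hazard ratios and per-cycle drug cost."""

    name: str
    hr_death: float = 1.0
    hr_hosp: float = 1.0
    hr_urgent: float = 1.0
    med_cost_per_cycle: float = 0.0

    @classmethod
    def standard(cls, params: ParameterSet) -> "ArmSpec":
        """Standard HFrEF therapy: all hazard ratios 1."""
        return cls("standard", med_cost_per_cycle=params.c_standard)

    @classmethod
    def dapagliflozin(cls, params: ParameterSet) -> "ArmSpec":
        """Dapagliflozin added on top of standard therapy."""
        return cls(
            "dapagliflozin",
            hr_death=params.hr_death.value,
            hr_hosp=params.hr_hosp.value,
            hr_urgent=params.hr_urgent.value,
            med_cost_per_cycle=params.c_standard + params.c_dapa,
        )


@dataclass(frozen=True)
class ExtraEvent:
    """A per-cycle transient event (e.g. a treatment adverse event) applied to
    the alive fraction, carrying a one-off cost and disutility but no state
    change."""

    name: str
    prob_per_cycle: float
    cost: float
    disutility: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob_per_cycle <= 1.0:
            raise ValueError(f"{self.name}: per-cycle probability outside [0, 1]")
        if self.cost < 0:
            raise ValueError(f"{self.name}: event cost must be >= 0")
        if self.disutility > 0:
            raise ValueError(f"{self.name}: disutility must be <= 0")


def escalate_hosp_prob(p_base: float, cycles_elapsed: int,
                       annual_factor: float) -> float:
    """Age-escalated quarterly hospitalization probability.

    The baseline quarterly rate is multiplied by ``annual_factor`` raised to
    the years elapsed (``cycles_elapsed / 4``) and converted back to a
    probability, which keeps the escalation composable with hazard-ratio
    scaling on the rate scale.
    """
    if not 0.0 <= p_base < 1.0:
        raise ValueError(f"baseline probability outside [0, 1): {p_base}")
    if annual_factor < 1.0:
        raise ValueError("annual escalation factor must be >= 1")
    rate = prob_to_rate(p_base, 1.0)  # per-cycle rate (t cancels below)
    return min(1.0, -math.expm1(-rate * annual_factor ** (cycles_elapsed / 4.0)))


def cycle_utility(base_utility: float, cycle_index: int,
                  decrement: float = 0.00174) -> float:
    """Utility of the alive states at a cycle: the baseline value decays by a
    constant relative fraction per quarter (aging and disease progression)."""
    if not 0.0 <= base_utility <= 1.0:
        raise ValueError("baseline utility must be in [0, 1]")
    return base_utility * (1.0 - decrement) ** cycle_index


def _step(stable: float, post: float, dead: float,
          p_death: float, p_hosp: float, p_inhosp: float,
          p_urgent: float, p_readmit: float):
    """One Markov transition; returns new occupancy and expected event counts."""
    for name, p in (("death", p_death), ("hospitalization", p_hosp),
                    ("in-hospital death", p_inhosp), ("urgent visit", p_urgent),
                    ("readmission", p_readmit)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"model integrity: {name} probability {p} outside [0, 1]")

    stable_surv = stable * (1.0 - p_death)
    post_surv = post * (1.0 - p_death)
    admissions = stable_surv * p_hosp
    readmissions = post_surv * p_readmit
    in_hosp_deaths = (admissions + readmissions) * p_inhosp
    urgent = stable_surv * (1.0 - p_hosp) * p_urgent

    new_stable = stable_surv * (1.0 - p_hosp) + post_surv * (1.0 - p_readmit)
    new_post = (admissions + readmissions) * (1.0 - p_inhosp)
    new_dead = dead + (stable + post) * p_death + in_hosp_deaths
    return (new_stable, new_post, new_dead), {
        "admissions": admissions,
        "readmissions": readmissions,
        "in_hosp_deaths": in_hosp_deaths,
        "urgent_visits": urgent,
    }


def cycle_transition(occupancy: tuple[float, float, float], cycle_index: int,
                     arm: ArmSpec, params: ParameterSet, table: LifeTable):
    """Single-cycle transition from ``(stable, post_hosp, dead)`` occupancy.

    Returns the new occupancy and the expected per-capita event counts for
    the cycle.  This is the scalar reference path; :func:`run_cohort`
    precomputes the same per-cycle probabilities in bulk.
    """
    s, p, d = occupancy
    if abs(s + p + d - 1.0) > 1e-9:
        raise ValueError("occupancy must sum to 1")
    age = params.start_age + params.cycle_length * cycle_index
    p_death = adjusted_quarterly_death_prob(
        table, age, params.mortality_rate_ratio * params.mortality_scale,
        arm.hr_death)
    p_hosp = apply_hazard_ratio(
        escalate_hosp_prob(params.p_hosp, cycle_index, params.hosp_escalation),
        arm.hr_hosp)
    p_urgent = apply_hazard_ratio(params.p_urgent, arm.hr_urgent)
    return _step(s, p, d, p_death, p_hosp, params.p_inhosp_death,
                 p_urgent, params.p_readmit)


@dataclass
class CohortTrace:
    """Per-cycle record of one arm's cohort run, scaled to the cohort size.

    Occupancy columns are cohort fractions; event counts and cost/effect
    columns are totals over the configured cohort size.
    """

    arm: str
    cohort_size: int
    cycle: np.ndarray = field(repr=False)
    age: np.ndarray = field(repr=False)
    stable: np.ndarray = field(repr=False)
    post_hosp: np.ndarray = field(repr=False)
    dead: np.ndarray = field(repr=False)
    admissions: np.ndarray = field(repr=False)
    readmissions: np.ndarray = field(repr=False)
    urgent_visits: np.ndarray = field(repr=False)
    in_hosp_deaths: np.ndarray = field(repr=False)
    extra_events: np.ndarray = field(repr=False)
    ly: np.ndarray = field(repr=False)
    qaly: np.ndarray = field(repr=False)
    cost_med: np.ndarray = field(repr=False)
    cost_hosp: np.ndarray = field(repr=False)
    cost_urgent: np.ndarray = field(repr=False)
    cost_extra: np.ndarray = field(repr=False)
    ly_disc: np.ndarray = field(repr=False)
    qaly_disc: np.ndarray = field(repr=False)
    cost_med_disc: np.ndarray = field(repr=False)
    cost_hosp_disc: np.ndarray = field(repr=False)
    cost_urgent_disc: np.ndarray = field(repr=False)
    cost_extra_disc: np.ndarray = field(repr=False)

    # -- totals -------------------------------------------------------------
    @property
    def hospitalizations(self) -> np.ndarray:
        """Admissions plus readmissions, per cycle (both carry the same cost
        and disutility)."""
        return self.admissions + self.readmissions

    @property
    def total_hospitalizations(self) -> float:
        return float(self.hospitalizations.sum())

    @property
    def total_urgent_visits(self) -> float:
        return float(self.urgent_visits.sum())

    @property
    def total_ly(self) -> float:
        return float(self.ly.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly.sum())

    @property
    def total_ly_disc(self) -> float:
        return float(self.ly_disc.sum())

    @property
    def total_qaly_disc(self) -> float:
        return float(self.qaly_disc.sum())

    @property
    def total_cost_med_disc(self) -> float:
        return float(self.cost_med_disc.sum())

    @property
    def total_cost_hosp_disc(self) -> float:
        return float(self.cost_hosp_disc.sum())

    @property
    def total_cost_urgent_disc(self) -> float:
        return float(self.cost_urgent_disc.sum())

    @property
    def total_cost_extra_disc(self) -> float:
        return float(self.cost_extra_disc.sum())

    @property
    def total_cost_disc(self) -> float:
        return (self.total_cost_med_disc + self.total_cost_hosp_disc
                + self.total_cost_urgent_disc + self.total_cost_extra_disc)

    @property
    def total_cost(self) -> float:
        return float(self.cost_med.sum() + self.cost_hosp.sum()
                     + self.cost_urgent.sum() + self.cost_extra.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle": self.cycle,
            "age": self.age,
            "stable": self.stable,
            "post_hosp": self.post_hosp,
            "dead": self.dead,
            "hospitalizations": self.hospitalizations,
            "urgent_visits": self.urgent_visits,
            "readmissions": self.readmissions,
            "in_hosp_deaths": self.in_hosp_deaths,
            "ly_disc": self.ly_disc,
            "qaly_disc": self.qaly_disc,
            "cost_med_disc": self.cost_med_disc,
            "cost_hosp_disc": self.cost_hosp_disc,
            "cost_urgent_disc": self.cost_urgent_disc,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_cohort(arm: ArmSpec, params: ParameterSet, table: LifeTable,
               horizon_years: float | None = None,
               extra_events: Sequence[ExtraEvent] = ()) -> CohortTrace:
    """Run the Markov cohort for one arm and return its full trace.

    ``horizon_years=None`` means a lifetime horizon: the run stops at
    ``params.max_age`` or when the alive fraction falls below 1e-9.  A finite
    horizon truncates accumulation with no terminal-state valuation.
    ``extra_events`` attach per-cycle transient events (adverse-event
    scenarios) to the alive fraction.
    """
    if horizon_years is not None and horizon_years <= 0:
        raise ValueError("horizon must be positive")
    dt = params.cycle_length
    if horizon_years is None:
        n_cycles = int(math.ceil((params.max_age - params.start_age) / dt))
        lifetime = True
    else:
        n_cycles = int(round(horizon_years / dt))
        lifetime = False

    k = np.arange(n_cycles)
    ages = params.start_age + dt * k
    rr = params.mortality_rate_ratio * params.mortality_scale
    p_death = -np.expm1(-table.rate_vector(ages) * rr * arm.hr_death * dt)
    p_death = np.minimum(p_death, 1.0)
    hosp_rate0 = -math.log1p(-params.p_hosp)  # per-cycle rate equivalent
    p_hosp = -np.expm1(-hosp_rate0 * params.hosp_escalation ** (k * dt)
                       * arm.hr_hosp)
    p_hosp = np.minimum(p_hosp, 1.0)
    p_urgent = apply_hazard_ratio(params.p_urgent, arm.hr_urgent)
    utility = params.u_base * (1.0 - params.utility_decrement_per_cycle) ** k
    discount = (1.0 + params.discount_rate) ** (-dt * k)
    pih = params.p_inhosp_death
    pr = params.p_readmit
    extra_p = np.array([e.prob_per_cycle for e in extra_events])
    extra_cost = np.array([e.cost for e in extra_events])
    extra_du = np.array([e.disutility for e in extra_events])

    cols = {name: np.zeros(n_cycles) for name in (
        "stable", "post_hosp", "dead", "admissions", "readmissions",
        "urgent_visits", "in_hosp_deaths", "extra_events",
        "ly", "qaly", "cost_med", "cost_hosp", "cost_urgent", "cost_extra")}

    s, p, d = 1.0, 0.0, 0.0
    used = n_cycles
    for i in range(n_cycles):
        alive_start = s + p
        (s, p, d), ev = _step(s, p, d, float(p_death[i]), float(p_hosp[i]),
                              pih, p_urgent, pr)
        if abs(s + p + d - 1.0) > _CONSERVATION_TOL:
            raise ValueError("model integrity: occupancy drifted from 1")
        alive = s + p
        occ = 0.5 * (alive_start + alive) if params.half_cycle_correction else alive
        hosp = ev["admissions"] + ev["readmissions"]
        urg = ev["urgent_visits"]
        n_extra = float((occ * extra_p).sum()) if len(extra_p) else 0.0
        qaly = (occ * utility[i] * dt + hosp * params.du_hosp
                + urg * params.du_urgent)
        if len(extra_p):
            qaly += float((occ * extra_p * extra_du).sum())

        cols["stable"][i] = s
        cols["post_hosp"][i] = p
        cols["dead"][i] = d
        cols["admissions"][i] = ev["admissions"]
        cols["readmissions"][i] = ev["readmissions"]
        cols["urgent_visits"][i] = urg
        cols["in_hosp_deaths"][i] = ev["in_hosp_deaths"]
        cols["extra_events"][i] = n_extra
        cols["ly"][i] = occ * dt
        cols["qaly"][i] = qaly
        cols["cost_med"][i] = occ * arm.med_cost_per_cycle
        cols["cost_hosp"][i] = hosp * params.c_hosp
        cols["cost_urgent"][i] = urg * params.c_urgent
        cols["cost_extra"][i] = (float((occ * extra_p * extra_cost).sum())
                                 if len(extra_p) else 0.0)
        if lifetime and alive < ALIVE_EPSILON:
            used = i + 1
            break

    sl = slice(0, used)
    n = params.cohort_size
    per_event = ("admissions", "readmissions", "urgent_visits",
                 "in_hosp_deaths", "extra_events",
                 "ly", "qaly", "cost_med", "cost_hosp", "cost_urgent",
                 "cost_extra")
    out = {name: cols[name][sl] for name in ("stable", "post_hosp", "dead")}
    out.update({name: cols[name][sl] * n for name in per_event})
    df = discount[sl]
    return CohortTrace(
        arm=arm.name,
        cohort_size=n,
        cycle=k[sl],
        age=ages[sl],
        **out,
        ly_disc=out["ly"] * df,
        qaly_disc=out["qaly"] * df,
        cost_med_disc=out["cost_med"] * df,
        cost_hosp_disc=out["cost_hosp"] * df,
        cost_urgent_disc=out["cost_urgent"] * df,
        cost_extra_disc=out["cost_extra"] * df,
    )
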