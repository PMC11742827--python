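"""Individual-level Monte Carlo oracle for the cohort engine.

Simulates each patient's quarterly trajectory by sampling the same per-cycle
event probabilities the cohort model uses (background death first, then
hospitalization with in-hospital fatality, then urgent visits; readmission
from the post-hospitalization state).  Means over many simulated patients
estimate the cohort engine's expected per-capita results, giving an
independent cross-check of the deterministic expectation calculation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hfcea import (
    ArmSpec,
    LifeTable,
    ParameterSet,
    apply_hazard_ratio,
    escalate_hosp_prob,
    rate_to_prob,
)

STABLE, POST, DEAD = 0, 1, 2


@dataclass
class MicrosimResult:
    """Per-patient discounted totals from the individual-level simulation."""

    ly: np.ndarray
    qaly: np.ndarray
    cost: np.ndarray
    hospitalizations: np.ndarray

    def mean_and_se(self, attr: str) -> tuple[float, float]:
        x = getattr(self, attr)
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x)))


def microsimulate(arm: ArmSpec, params: ParameterSet, table: LifeTable,
                  n_patients: int, seed: int) -> MicrosimResult:
    rng = np.random.default_rng(seed)
    dt = params.cycle_length
    n_cycles = int(np.ceil((params.max_age - params.start_age) / dt))
    rr = params.mortality_rate_ratio * params.mortality_scale

    p_death = np.array([
        min(1.0, rate_to_prob(
            table.rate(params.start_age + dt * k) * rr * arm.hr_death, dt))
        for k in range(n_cycles)
    ])
    p_hosp = np.array([
        apply_hazard_ratio(
            escalate_hosp_prob(params.p_hosp, k, params.hosp_escalation),
            arm.hr_hosp)
        for k in range(n_cycles)
    ])
    p_urgent = apply_hazard_ratio(params.p_urgent, arm.hr_urgent)
    utility = params.u_base * (1 - params.utility_decrement_per_cycle) ** np.arange(n_cycles)
    discount = (1 + params.discount_rate) ** (-dt * np.arange(n_cycles))

    state = np.full(n_patients, STABLE, dtype=np.int8)
    ly = np.zeros(n_patients)
    qaly = np.zeros(n_patients)
    cost = np.zeros(n_patients)
    hosps = np.zeros(n_patients)

    for k in range(n_cycles):
        alive = state != DEAD
        if not alive.any():
            break
        # background death first, both alive states
        dies = alive & (rng.random(n_patients) < p_death[k])
        state[dies] = DEAD

        stable = state == STABLE
        post = state == POST

        admitted = stable & (rng.random(n_patients) < p_hosp[k])
        readmitted = post & (rng.random(n_patients) < params.p_readmit)
        hosp_event = admitted | readmitted
        hosp_dies = hosp_event & (rng.random(n_patients) < params.p_inhosp_death)
        state[hosp_event] = POST
        state[hosp_dies] = DEAD
        state[post & ~readmitted] = STABLE

        urgent = stable & ~admitted & (rng.random(n_patients) < p_urgent)

        alive_end = state != DEAD
        df = discount[k]
        ly += alive_end * dt * df
        q = alive_end * utility[k] * dt
        q = q + hosp_event * params.du_hosp + urgent * params.du_urgent
        qaly += q * df
        c = (alive_end * arm.med_cost_per_cycle
             + hosp_event * params.c_hosp + urgent * params.c_urgent)
        cost += c * df
        hosps += hosp_event

    return MicrosimResult(ly=ly, qaly=qaly, cost=cost, hospitalizations=hosps)
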