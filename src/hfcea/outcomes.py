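"""Incremental cost-effectiveness analysis of two arm traces.

Produces per-arm totals, their increments, the three incremental
cost-effectiveness ratios (per QALY gained, per life-year saved, per
hospitalization avoided) and the net monetary benefit at a willingness-to-pay
threshold.  Ratios are computed from unrounded totals; report exports round
for presentation only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cohort import CohortTrace

__all__ = ["ArmTotals", "CEResults", "incremental_analysis"]


@dataclass(frozen=True)
class ArmTotals:
    """Discounted lifetime totals for one arm (cohort-scaled)."""

    name: str
    hospitalizations: float
    urgent_visits: float
    life_years: float
    qalys: float
    life_years_undisc: float
    qalys_undisc: float
    cost_medication: float
    cost_hospitalization: float
    cost_urgent: float
    cost_other: float

    @property
    def cost_total(self) -> float:
        return (self.cost_medication + self.cost_hospitalization
                + self.cost_urgent + self.cost_other)

    @classmethod
    def from_trace(cls, trace: CohortTrace) -> "ArmTotals":
        return cls(
            name=trace.arm,
            hospitalizations=trace.total_hospitalizations,
            urgent_visits=trace.total_urgent_visits,
            life_years=trace.total_ly_disc,
            qalys=trace.total_qaly_disc,
            life_years_undisc=trace.total_ly,
            qalys_undisc=trace.total_qaly,
            cost_medication=trace.total_cost_med_disc,
            cost_hospitalization=trace.total_cost_hosp_disc,
            cost_urgent=trace.total_cost_urgent_disc,
            cost_other=trace.total_cost_extra_disc,
        )


def _safe_ratio(delta_cost: float, delta_effect: float) -> float | None:
    """ICER for a positive effect gain; ``None`` (undefined/dominance) when
    the effect increment is not positive."""
    if delta_effect <= 0:
        return None
    return delta_cost / delta_effect


@dataclass(frozen=True)
class CEResults:
    """Incremental analysis of intervention vs comparator.

    ICERs are ``None`` when the corresponding effect increment is <= 0; the
    ``dominant`` flag marks the case of lower cost with greater effect, which
    must never be presented as a negative ratio.
    """

    intervention: ArmTotals
    comparator: ArmTotals
    wtp: float

    @property
    def delta_cost(self) -> float:
        return self.intervention.cost_total - self.comparator.cost_total

    @property
    def delta_qaly(self) -> float:
        return self.intervention.qalys - self.comparator.qalys

    @property
    def delta_ly(self) -> float:
        return self.intervention.life_years - self.comparator.life_years

    @property
    def hospitalizations_avoided(self) -> float:
        return self.comparator.hospitalizations - self.intervention.hospitalizations

    @property
    def urgent_visits_avoided(self) -> float:
        return self.comparator.urgent_visits - self.intervention.urgent_visits

    @property
    def icer_per_qaly(self) -> float | None:
        return _safe_ratio(self.delta_cost, self.delta_qaly)

    @property
    def icer_per_ly(self) -> float | None:
        return _safe_ratio(self.delta_cost, self.delta_ly)

    @property
    def icer_per_hosp_avoided(self) -> float | None:
        return _safe_ratio(self.delta_cost, self.hospitalizations_avoided)

    @property
    def nmb(self) -> float:
        """Net monetary benefit at the configured willingness-to-pay."""
        return self.wtp * self.delta_qaly - self.delta_cost

    @property
    def dominant(self) -> bool:
        """Intervention costs less and yields more QALYs."""
        return self.delta_cost < 0 and self.delta_qaly > 0

    @property
    def cost_effective(self) -> bool | None:
        """ICER at or below the threshold; ``None`` when the ICER is
        undefined and the intervention is not dominant."""
        if self.dominant:
            return True
        icer = self.icer_per_qaly
        if icer is None:
            return None
        return icer <= self.wtp

    def to_dict(self) -> dict:
        def arm(t: ArmTotals) -> dict:
            return {
                "hospitalizations": t.hospitalizations,
                "urgent_visits": t.urgent_visits,
                "life_years": t.life_years,
                "qalys": t.qalys,
                "life_years_undiscounted": t.life_years_undisc,
                "qalys_undiscounted": t.qalys_undisc,
                "cost_medication": t.cost_medication,
                "cost_hospitalization": t.cost_hospitalization,
                "cost_urgent": t.cost_urgent,
                "cost_other": t.cost_other,
                "cost_total": t.cost_total,
            }

        return {
            "intervention": arm(self.intervention),
            "comparator": arm(self.comparator),
            "increments": {
                "cost": self.delta_cost,
                "qalys": self.delta_qaly,
                "life_years": self.delta_ly,
                "hospitalizations_avoided": self.hospitalizations_avoided,
                "urgent_visits_avoided": self.urgent_visits_avoided,
            },
            "icer_per_qaly": self.icer_per_qaly,
            "icer_per_life_year": self.icer_per_ly,
            "icer_per_hospitalization_avoided": self.icer_per_hosp_avoided,
            "nmb": self.nmb,
            "wtp": self.wtp,
            "dominant": self.dominant,
            "cost_effective": self.cost_effective,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_table(self) -> pd.DataFrame:
        """Presentation table: rows = measures, columns = intervention,
        comparator, difference; currency and effects rounded to 2 d.p."""
        i, c = self.intervention, self.comparator
        rows = [
            ("Hospitalizations", i.hospitalizations, c.hospitalizations,
             -self.hospitalizations_avoided),
            ("Urgent care visits", i.urgent_visits, c.urgent_visits,
             -self.urgent_visits_avoided),
            ("Life-years", i.life_years, c.life_years, self.delta_ly),
            ("QALYs", i.qalys, c.qalys, self.delta_qaly),
            ("Medication costs", i.cost_medication, c.cost_medication,
             i.cost_medication - c.cost_medication),
            ("Hospitalization costs", i.cost_hospitalization,
             c.cost_hospitalization,
             i.cost_hospitalization - c.cost_hospitalization),
            ("Urgent care costs", i.cost_urgent, c.cost_urgent,
             i.cost_urgent - c.cost_urgent),
            ("Total costs", i.cost_total, c.cost_total, self.delta_cost),
        ]
        if i.cost_other or c.cost_other:
            rows.insert(-1, ("Other event costs", i.cost_other, c.cost_other,
                             i.cost_other - c.cost_other))

        def fmt(x: float | None) -> float | str:
            if x is None:
                return "undefined"
            return round(x, 2)

        df = pd.DataFrame(rows, columns=["measure", i.name, c.name, "difference"])
        for col in (i.name, c.name, "difference"):
            df[col] = df[col].round(2)
        extra = pd.DataFrame(
            [
                ("ICER per hospitalization avoided", "", "",
                 "dominant" if self.dominant else fmt(self.icer_per_hosp_avoided)),
                ("ICER per life-year saved", "", "",
                 "dominant" if self.dominant else fmt(self.icer_per_ly)),
                ("ICER per QALY gained", "", "",
                 "dominant" if self.dominant else fmt(self.icer_per_qaly)),
            ],
            columns=df.columns,
        )
        return pd.concat([df, extra], ignore_index=True)


def incremental_analysis(trace_intervention: CohortTrace,
                         trace_comparator: CohortTrace,
                         wtp: float = 8000.0) -> CEResults:
    """Compare two traces run under identical settings except the arm."""
    if trace_intervention.cohort_size != trace_comparator.cohort_size:
        raise ValueError("traces must use the same cohort size")
    return CEResults(
        intervention=ArmTotals.from_trace(trace_intervention),
        comparator=ArmTotals.from_trace(trace_comparator),
        wtp=wtp,
    )
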