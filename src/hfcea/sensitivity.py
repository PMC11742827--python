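"""Deterministic (tornado) and probabilistic sensitivity analysis.

The tornado analysis re-runs the model twice per parameter -- once at the low
and once at the high end of its 95% range -- holding everything else at the
base case, and sorts parameters by the width of the resulting ICER band.

The probabilistic sensitivity analysis (second-order Monte Carlo) draws every
varied parameter simultaneously from its fitted distribution (beta for
probabilities and utilities, gamma for costs, log-normal for hazard ratios),
re-runs both arms per draw, and summarizes the incremental cost/QALY cloud as
the fraction of draws that are cost-effective at the willingness-to-pay
threshold and as a cost-effectiveness acceptability curve (CEAC).

Sampling uses a single RNG stream with a fixed, documented parameter order
(:data:`hfcea.parameters.SENSITIVITY_PARAMETERS`), so results are exactly
reproducible for a given seed and draw count; adding a parameter changes all
downstream draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import ArmSpec, run_cohort
from .life_table import LifeTable
from .outcomes import incremental_analysis
from .parameters import (
    SENSITIVITY_PARAMETERS,
    DistributionSpec,
    HazardRatio,
    ParameterSet,
    default_ranges,
    fit_all_distributions,
    prob_to_rate,
)

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "CEAC",
    "set_sensitivity_value",
    "base_case_icer",
    "tornado",
    "run_psa",
    "ceac",
]


def set_sensitivity_value(params: ParameterSet, name: str,
                          value: float) -> ParameterSet:
    """Return a parameter set with one sensitivity parameter replaced.

    Hazard ratios are replaced by a point value (CI collapsed).  The
    first-cycle death probability is translated into a multiplier on the
    background mortality rate so the whole age profile shifts with it on the
    rate scale.
    """
    if name not in SENSITIVITY_PARAMETERS:
        raise KeyError(f"unknown sensitivity parameter {name!r}")
    if name.startswith("hr_"):
        return params.with_overrides(**{name: HazardRatio(value, value, value)})
    if name == "p_death_cycle1":
        scale = (prob_to_rate(value, params.cycle_length)
                 / prob_to_rate(params.p_death_cycle1, params.cycle_length))
        return params.with_overrides(
            p_death_cycle1=value,
            mortality_scale=params.mortality_scale * scale,
        )
    return params.with_overrides(**{name: value})


def _run_increments(params: ParameterSet, table: LifeTable,
                    horizon_years: float | None = None):
    dapa = run_cohort(ArmSpec.dapagliflozin(params), params, table, horizon_years)
    std = run_cohort(ArmSpec.standard(params), params, table, horizon_years)
    return incremental_analysis(dapa, std, wtp=params.wtp)


def base_case_icer(params: ParameterSet, table: LifeTable) -> float | None:
    """Lifetime base-case ICER per QALY (convenience wrapper)."""
    return _run_increments(params, table).icer_per_qaly


# ---------------------------------------------------------------------------
# tornado
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    """One bar of the tornado diagram."""

    parameter: str
    low: float
    high: float
    icer_low: float | None    # ICER with the parameter at its low input
    icer_high: float | None   # ICER with the parameter at its high input
    flagged: bool = False     # a variation produced a non-positive QALY gain

    @property
    def bandwidth(self) -> float:
        if self.icer_low is None or self.icer_high is None:
            return math.inf  # sorts first; flagged for inspection
        return abs(self.icer_high - self.icer_low)


def tornado(params: ParameterSet, table: LifeTable,
            ranges: Mapping[str, tuple[float, float]] | None = None,
            horizon_years: float | None = None) -> list[TornadoEntry]:
    """One-way deterministic sensitivity analysis over every varied parameter.

    Returns entries sorted by ICER bandwidth, widest first.  Variations whose
    QALY increment is not positive yield an undefined ICER and are flagged
    rather than dropped.
    """
    if ranges is None:
        ranges = default_ranges(params)
    entries: list[TornadoEntry] = []
    for name in SENSITIVITY_PARAMETERS:
        if name not in ranges:
            continue
        lo, hi = ranges[name]
        icers: list[float | None] = []
        for v in (lo, hi):
            res = _run_increments(set_sensitivity_value(params, name, v),
                                  table, horizon_years)
            icers.append(res.icer_per_qaly)
        entries.append(TornadoEntry(
            parameter=name, low=lo, high=hi,
            icer_low=icers[0], icer_high=icers[1],
            flagged=icers[0] is None or icers[1] is None,
        ))
    entries.sort(key=lambda e: e.bandwidth, reverse=True)
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "bandwidth": e.bandwidth,
                "flagged": e.flagged,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSAResult:
    """Per-draw incremental results of a second-order Monte Carlo run."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    nmb: np.ndarray
    seed: int
    wtp: float
    n_clipped: int = 0

    @property
    def n(self) -> int:
        return len(self.delta_cost)

    @property
    def icer(self) -> np.ndarray:
        """Per-draw ICER; NaN where the QALY increment is <= 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(self.delta_qaly > 0,
                           self.delta_cost / self.delta_qaly, np.nan)
        return out

    @property
    def fraction_cost_effective(self) -> float:
        """Share of draws with positive net monetary benefit at ``wtp``."""
        return float(np.mean(self.nmb > 0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "draw": np.arange(self.n),
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "nmb": self.nmb,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def sample_parameter_draws(specs: Mapping[str, DistributionSpec],
                           n_draws: int, rng: np.random.Generator,
                           ) -> dict[str, np.ndarray]:
    """Draw all parameters for ``n_draws`` iterations.

    One vectorized draw per parameter, in the canonical order, from a single
    RNG stream -- the documented reproducibility contract of the PSA.
    """
    return {name: np.asarray(specs[name].sample(rng, n_draws))
            for name in SENSITIVITY_PARAMETERS if name in specs}


_PROB_CLIP = 1.0 - 1e-9


def run_psa(params: ParameterSet, table: LifeTable, n_draws: int = 10_000,
            seed: int = 0, wtp: float | None = None,
            horizon_years: float | None = None,
            specs: Mapping[str, DistributionSpec] | None = None) -> PSAResult:
    """Second-order Monte Carlo over all varied parameters.

    Each draw samples the full parameter vector, runs both arms, and records
    the incremental cost and QALYs.  Sampled probabilities that reach 1 are
    clipped just below it (counted in ``n_clipped``); downstream cycle
    probabilities are capped inside the engine.  ``specs`` replaces the
    default fitted distributions (e.g. degenerate point masses for a
    zero-variance run).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if wtp is None:
        wtp = params.wtp
    rng = np.random.default_rng(seed)
    if specs is None:
        specs = fit_all_distributions(params)
    draws = sample_parameter_draws(specs, n_draws, rng)

    n_clipped = 0
    for name, arr in draws.items():
        if name.startswith(("p_", "u_")):
            over = arr >= 1.0
            if over.any():
                n_clipped += int(over.sum())
                arr[over] = _PROB_CLIP

    delta_cost = np.empty(n_draws)
    delta_qaly = np.empty(n_draws)
    for i in range(n_draws):
        p_i = params
        for name in SENSITIVITY_PARAMETERS:
            if name in draws:
                p_i = set_sensitivity_value(p_i, name, float(draws[name][i]))
        res = _run_increments(p_i, table, horizon_years)
        delta_cost[i] = res.delta_cost
        delta_qaly[i] = res.delta_qaly

    nmb = wtp * delta_qaly - delta_cost
    return PSAResult(delta_cost=delta_cost, delta_qaly=delta_qaly, nmb=nmb,
                     seed=seed, wtp=wtp, n_clipped=n_clipped)


# ---------------------------------------------------------------------------
# acceptability curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CEAC:
    """Probability of cost-effectiveness over a willingness-to-pay grid."""

    wtp: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp,
                             "prob_cost_effective": self.probability})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def ceac(psa: PSAResult, wtp_grid: np.ndarray | None = None) -> CEAC:
    """Pointwise acceptability curve from an existing draw set (no
    re-simulation): at each threshold w, the fraction of draws with
    ``w * dQALY - dCost > 0``."""
    if psa.n == 0:
        raise ValueError("PSA result is empty")
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 20_000.0 + 1, 500.0)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if len(wtp_grid) == 0 or np.any(np.diff(wtp_grid) <= 0):
        raise ValueError("WTP grid must be non-empty and strictly increasing")
    nb = wtp_grid[:, None] * psa.delta_qaly[None, :] - psa.delta_cost[None, :]
    return CEAC(wtp=wtp_grid, probability=(nb > 0).mean(axis=1))


# ---------------------------------------------------------------------------
# optional figures
# ---------------------------------------------------------------------------

def plot_tornado(entries: Sequence[TornadoEntry], base_icer: float, path=None):
    """Horizontal-bar tornado diagram (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    drawable = [e for e in entries if not e.flagged][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(drawable) + 1.5))
    for y, e in enumerate(drawable):
        lo, hi = sorted((e.icer_low, e.icer_high))
        ax.barh(y, hi - lo, left=lo, color="#4878d0")
    ax.axvline(base_icer, color="k", lw=1)
    ax.set_yticks(range(len(drawable)))
    ax.set_yticklabels([e.parameter for e in drawable])
    ax.set_xlabel("ICER (US$/QALY)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_ce_plane(psa: PSAResult, path=None):
    """Incremental cost vs QALY scatter with the WTP threshold line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa.delta_qaly, psa.delta_cost, s=4, alpha=0.3)
    q = np.array([min(0, psa.delta_qaly.min()), psa.delta_qaly.max()])
    ax.plot(q, psa.wtp * q, "r--", lw=1, label=f"WTP = {psa.wtp:,.0f} $/QALY")
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (US$)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_ceac(curve: CEAC, path=None):
    """Acceptability curve figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.wtp, curve.probability)
    ax.set_xlabel("Willingness-to-pay (US$/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
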