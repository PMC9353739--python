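"""Discounted cost and QALY accrual over a Markov trace, and incremental
cost-effectiveness.

Costing follows the published schedule: during progression-free cycles the
arm's drug, pretreatment and administration costs accrue by phase (4-cycle
platinum induction, pemetrexed maintenance, a 34-cycle camrelizumab cap in
the combination arm); progressed-disease cycles accrue the second-line
therapy cost; every alive cycle accrues disease management (higher tariff
for the first 18 model cycles); the grade >=3 adverse-event management cost
is a single lump charged at cycle 1.  Costs attach to start-of-cycle
occupancy with no half-cycle correction, discounted at the annual rate from
the moment each cycle's treatment starts (cycle 1 is undiscounted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .markov import MarkovTrace
from .params import DAYS_PER_YEAR, ModelSettings, StrategySpec

__all__ = [
    "CEResult",
    "discount_factor",
    "cycle_cost",
    "accrue",
    "compute_icer",
    "expected_ae_cost",
]


@dataclass(frozen=True)
class CEResult:
    """Base-case (or one re-run's) cost-effectiveness summary.

    ``icer`` is cost per QALY of the combination over chemotherapy alone;
    it is NaN (with ``icer_defined`` False) when the QALY increment is zero,
    and negative under dominance (``dominance`` labels the quadrant).
    """

    combo_cost: float
    combo_qalys: float
    chemo_cost: float
    chemo_qalys: float
    delta_cost: float
    delta_qalys: float
    icer: float
    icer_defined: bool
    wtp_per_qaly: float
    cost_effective: bool
    dominance: str = ""

    def verdict(self) -> str:
        if not self.icer_defined:
            return "ICER undefined (zero QALY increment)"
        relation = "<=" if self.icer <= self.wtp_per_qaly else ">"
        judgement = "" if self.cost_effective else "not "
        return (
            f"ICER {self.icer:,.2f} USD/QALY {relation} WTP "
            f"{self.wtp_per_qaly:,.2f}: combination therapy is "
            f"{judgement}cost-effective"
        )


def discount_factor(cycle: int, settings: ModelSettings) -> float:
    """(1 + r)^(-cycle * cycle_length/365.25); 1 at cycle 0."""
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    years = cycle * settings.cycle_length_days / DAYS_PER_YEAR
    return (1.0 + settings.annual_discount_rate) ** (-years)


def cycle_cost(arm: StrategySpec, state: str, cycle: int) -> float:
    """Cost (USD) accrued by one person spending cycle ``cycle`` in ``state``.

    The progressed-disease cost is the arm's full second-line schedule per
    cycle (``second_line_cost_per_cycle``) plus disease management; death
    costs nothing.  The adverse-event lump is handled in :func:`accrue`,
    not here.
    """
    if cycle < 1:
        raise ValueError("cycle must be >= 1")
    if state == "dead":
        return 0.0
    dm = arm.dm_early if cycle <= arm.dm_breakpoint else arm.dm_late
    if state == "pd":
        return arm.second_line_cost_per_cycle + dm
    if state != "pfs":
        raise ValueError(f"unknown state {state!r}")
    cost = arm.pemetrexed_cost + arm.pretreatment_cost + dm
    cap = arm.camrelizumab_max_cycles
    if cycle <= arm.induction_cycles:
        cost += arm.carboplatin_cost + arm.admin_induction
        if cap is not None:
            cost += arm.camrelizumab_cost
    elif cap is None or cycle <= cap:
        cost += arm.admin_maintenance
        if cap is not None:
            cost += arm.camrelizumab_cost
    else:
        cost += arm.admin_post_cap
    return cost


def accrue(
    trace: MarkovTrace, arm: StrategySpec, settings: ModelSettings
) -> tuple[float, float]:
    """Discounted (cost USD, QALYs) for one arm over the full horizon.

    Cycle u (u = 1..horizon) accrues start-of-cycle occupancy (trace row
    u-1) at discount_factor(u-1), so the first cycle is undiscounted; QALY
    weight is utility x cycle length in years.  The adverse-event lump cost
    is added at cycle 1 (discount factor 1).
    """
    h = settings.horizon_cycles
    if trace.horizon_cycles != h:
        raise ValueError(
            f"trace horizon {trace.horizon_cycles} != settings horizon {h}"
        )
    cycles = np.arange(1, h + 1)
    df = (1.0 + settings.annual_discount_rate) ** (
        -(cycles - 1) * settings.cycle_length_days / DAYS_PER_YEAR
    )
    pfs_occ = trace.pfs[:h]
    pd_occ = trace.pd[:h]
    pfs_costs = np.array([cycle_cost(arm, "pfs", int(u)) for u in cycles])
    pd_costs = np.array([cycle_cost(arm, "pd", int(u)) for u in cycles])
    cost = arm.ae_lump_cost + float(np.sum(df * (pfs_occ * pfs_costs + pd_occ * pd_costs)))
    cycle_years = settings.cycle_length_days / DAYS_PER_YEAR
    qalys = float(
        np.sum(df * (pfs_occ * arm.utility_pfs + pd_occ * arm.utility_pd)) * cycle_years
    )
    return cost, qalys


def compute_icer(
    combo: tuple[float, float],
    chemo: tuple[float, float],
    wtp: float,
) -> CEResult:
    """Incremental cost-effectiveness of the combination over chemotherapy.

    ``combo`` and ``chemo`` are (discounted cost, discounted QALYs) pairs.
    """
    combo_cost, combo_q = combo
    chemo_cost, chemo_q = chemo
    d_cost = combo_cost - chemo_cost
    d_q = combo_q - chemo_q
    defined = d_q != 0.0
    icer = d_cost / d_q if defined else math.nan
    dominance = ""
    if d_q > 0 and d_cost <= 0:
        dominance = "combination dominant (cheaper, more effective)"
    elif d_q < 0 and d_cost >= 0:
        dominance = "combination dominated (costlier, less effective)"
    cost_effective = bool(d_q > 0 and (d_cost <= 0 or icer <= wtp))
    return CEResult(
        combo_cost=combo_cost,
        combo_qalys=combo_q,
        chemo_cost=chemo_cost,
        chemo_qalys=chemo_q,
        delta_cost=d_cost,
        delta_qalys=d_q,
        icer=icer,
        icer_defined=defined,
        wtp_per_qaly=wtp,
        cost_effective=cost_effective,
        dominance=dominance,
    )


def expected_ae_cost(
    incidences: list[tuple[str, float]],
    unit_costs: list[tuple[str, float]],
) -> float:
    """Expected adverse-event management cost: sum of incidence x unit cost.

    Helper for regenerating the lump adverse-event rows from grade >=3
    event incidences and user-supplied per-event management costs.  Every
    incidence event must have a matching unit cost (by name).
    """
    cost_map = dict(unit_costs)
    missing = [name for name, _ in incidences if name not in cost_map]
    if missing:
        raise KeyError(f"no unit cost for event(s): {', '.join(missing)}")
    return float(sum(rate * cost_map[name] for name, rate in incidences))
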