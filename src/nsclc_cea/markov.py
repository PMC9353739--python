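"""Three-state Markov cohort engine: progression-free (PFS), progressed
disease (PD), and death (absorbing).

The cohort starts fully progression-free.  Two engine modes are provided:

``transition`` (default)
    Cycle-by-cycle state transitions.  The PFS exit probability comes from
    the fitted PFS curve; a background (all-cause) mortality probability is
    routed PFS -> death and the remainder PFS -> PD; the PD -> death
    probability is calibrated each cycle so that cumulative deaths track the
    fitted overall-survival curve 1 - S_os(t).

``occupancy``
    Partitioned-survival identities evaluated directly: PFS(t) = S_pfs(t),
    PD(t) = max(0, S_os(t) - S_pfs(t)), death(t) = 1 - S_os(t).

Because the transition engine is calibrated to the same OS curve, the two
modes agree to rounding wherever no probability clipping occurs; clip events
(possible when independently fitted curves cross) are counted and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .params import ModelSettings, WeibullParams
from .survival import annual_prob_to_period, weibull_survival

__all__ = ["MarkovTrace", "TraceSummary", "build_trace", "trace_summary"]

logger = logging.getLogger(__name__)

STATES = ("pfs", "pd", "dead")


@dataclass(frozen=True)
class MarkovTrace:
    """State occupancy per cycle: rows 0..horizon, columns (pfs, pd, dead)."""

    occupancy: np.ndarray
    arm: str
    mode: str
    clip_events: int = 0

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        if occ.ndim != 2 or occ.shape[1] != 3:
            raise ValueError("occupancy must be (horizon+1) x 3")
        if np.any(occ < -1e-12) or np.any(occ > 1.0 + 1e-12):
            raise ValueError("occupancies must lie in [0, 1]")
        if np.max(np.abs(occ.sum(axis=1) - 1.0)) > 1e-10:
            raise ValueError("every row of a Markov trace must sum to 1")

    @property
    def horizon_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def pfs(self) -> np.ndarray:
        return self.occupancy[:, 0]

    @property
    def pd(self) -> np.ndarray:
        return self.occupancy[:, 1]

    @property
    def dead(self) -> np.ndarray:
        return self.occupancy[:, 2]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cycle": np.arange(self.occupancy.shape[0]),
                "pfs": self.pfs,
                "pd": self.pd,
                "dead": self.dead,
            }
        )


@dataclass(frozen=True)
class TraceSummary:
    """Undiscounted person-cycle totals and absorption summary for one arm."""

    arm: str
    pfs_cycles: float
    pd_cycles: float
    life_cycles: float
    mean_cycles_to_death: float
    fraction_dead_at_horizon: float


def build_trace(
    pfs: WeibullParams,
    os: WeibullParams,
    settings: ModelSettings,
    mode: str = "transition",
    arm: str | None = None,
) -> MarkovTrace:
    """Run the cohort over ``settings.horizon_cycles`` cycles.

    ``pfs`` and ``os`` are the fitted progression-free and overall survival
    parameters for one arm, on the cycle time scale.
    """
    if mode not in ("transition", "occupancy"):
        raise ValueError(f"unknown engine mode {mode!r}")
    horizon = settings.horizon_cycles
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    arm = arm or pfs.arm
    t = np.arange(horizon + 1, dtype=float)
    s_pfs = np.asarray(weibull_survival(pfs, t))
    s_os = np.asarray(weibull_survival(os, t))

    if mode == "occupancy":
        pd_occ = s_os - s_pfs
        clips = int(np.count_nonzero(pd_occ < 0))
        if clips:
            logger.warning(
                "arm %s: OS curve below PFS curve at %d cycles; PD floored at 0",
                arm,
                clips,
            )
        pd_occ = np.maximum(0.0, pd_occ)
        # dead = 1 - pfs - pd: equals 1 - S_os except where the clip moved mass
        occ = np.column_stack([s_pfs, pd_occ, 1.0 - s_pfs - pd_occ])
        return MarkovTrace(occupancy=occ, arm=arm, mode=mode, clip_events=clips)

    bg_cycle = annual_prob_to_period(
        settings.background_annual_mortality, settings.cycle_length_days
    )
    occ = np.zeros((horizon + 1, 3))
    occ[0] = (1.0, 0.0, 0.0)
    clips = 0
    for u in range(1, horizon + 1):
        p_prev, d_prev, dead_prev = occ[u - 1]
        p_exit = 1.0 - s_pfs[u] / s_pfs[u - 1]
        p_pfs_death = min(bg_cycle, p_exit)
        p_pfs_pd = p_exit - p_pfs_death
        deaths_from_pfs = p_prev * p_pfs_death
        # patients progressing this cycle are at risk of dying within it
        # (jump-through transition); the PD->death probability is calibrated
        # so that cumulative deaths track 1 - S_os
        pd_pool = d_prev + p_prev * p_pfs_pd
        needed_pd_deaths = (1.0 - s_os[u]) - dead_prev - deaths_from_pfs
        if pd_pool > 0.0:
            p_pd_death = needed_pd_deaths / pd_pool
            if p_pd_death < -1e-12 or p_pd_death > 1.0 + 1e-12:
                clips += 1
                logger.warning(
                    "arm %s cycle %d: calibrated PD->death probability %.4g "
                    "clipped to [0, 1]",
                    arm,
                    u,
                    p_pd_death,
                )
            p_pd_death = min(1.0, max(0.0, p_pd_death))
        else:
            p_pd_death = 0.0
            if abs(needed_pd_deaths) > 1e-12:
                clips += 1
        occ[u, 0] = p_prev * (1.0 - p_exit)
        occ[u, 1] = pd_pool * (1.0 - p_pd_death)
        occ[u, 2] = dead_prev + deaths_from_pfs + pd_pool * p_pd_death
    return MarkovTrace(occupancy=occ, arm=arm, mode=mode, clip_events=clips)


def trace_summary(trace: MarkovTrace) -> TraceSummary:
    """Undiscounted person-cycles per state (start-of-cycle counting over
    cycles 1..horizon), mean time to absorption, and terminal mortality."""
    h = trace.horizon_cycles
    pfs_cycles = float(trace.pfs[:h].sum())
    pd_cycles = float(trace.pd[:h].sum())
    life = pfs_cycles + pd_cycles
    new_deaths = np.diff(trace.dead)
    cycles = np.arange(1, h + 1, dtype=float)
    absorbed = float(trace.dead[-1])
    mean_ttd = float((new_deaths * cycles).sum() / absorbed) if absorbed > 0 else float("inf")
    return TraceSummary(
        arm=trace.arm,
        pfs_cycles=pfs_cycles,
        pd_cycles=pd_cycles,
        life_cycles=life,
        mean_cycles_to_death=mean_ttd,
        fraction_dead_at_horizon=absorbed,
    )
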