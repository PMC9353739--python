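"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way analysis re-runs the full deterministic model at each parameter's
low and high bound with everything else at base; the camrelizumab price is
varied downward only.  Probabilistic analysis draws all cost and utility
parameters jointly (gamma for costs, beta for utilities, method-of-moments
from the base value and the low-high range; the discount rate stays fixed,
as do the fitted survival parameters), re-evaluates the model per draw, and
summarizes the draws as a cost-effectiveness acceptability curve (CEAC) via
the incremental net-monetary-benefit rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import accrue, compute_icer
from .markov import MarkovTrace, build_trace
from .params import ModelSettings, ParamDistribution, ParameterBundle

__all__ = [
    "OWSARow",
    "PSASample",
    "Sampler",
    "build_distribution",
    "evaluate_model",
    "run_owsa",
    "run_psa",
    "ceac",
    "owsa_frame",
    "psa_frame",
]

logger = logging.getLogger(__name__)

# The low-high range is read as base +/- RANGE_Z standard deviations.  The
# default 1.0 treats the bounds as one-sd price/utility variation (they are
# observed provincial extremes, not confidence-interval endpoints); 1.96
# would instead read the range as a 95% interval.
RANGE_Z = 1.0


@dataclass(frozen=True)
class OWSARow:
    """One tornado bar: ICERs with a single parameter at its bounds."""

    name: str
    low_input: float
    high_input: float
    icer_low: float
    icer_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_high - self.icer_low)


@dataclass(frozen=True)
class PSASample:
    """One probabilistic draw: sampled parameters and the resulting increments."""

    draw: int
    values: Mapping[str, float]
    delta_cost: float
    delta_qalys: float


@dataclass(frozen=True)
class Sampler:
    """A parameter's sampling distribution (method-of-moments gamma/beta/fixed)."""

    name: str
    family: str
    mean: float
    sd: float
    shape_a: float = 0.0
    shape_b: float = 0.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "fixed" or self.sd == 0.0:
            return np.full(size, self.mean)
        if self.family == "gamma":
            return rng.gamma(self.shape_a, self.shape_b, size=size)
        return rng.beta(self.shape_a, self.shape_b, size=size)


def build_distribution(p: ParamDistribution, range_z: float = RANGE_Z) -> Sampler:
    """Method-of-moments sampler for one parameter-table row.

    mean = base, sd = (high - low) / (2 * range_z).  Gamma: shape = mean^2/sd^2,
    scale = sd^2/mean.  Beta: alpha = mean * (mean(1-mean)/sd^2 - 1),
    beta = (1-mean) * (same).  ``fixed`` rows (and degenerate ranges) are
    point masses at base.
    """
    sd = (p.high - p.low) / (2.0 * range_z)
    if p.family == "fixed" or sd == 0.0:
        return Sampler(name=p.name, family="fixed", mean=p.base, sd=0.0)
    if p.family == "gamma":
        if p.base <= 0:
            raise ValueError(f"{p.name}: gamma requires a positive base value")
        return Sampler(
            name=p.name,
            family="gamma",
            mean=p.base,
            sd=sd,
            shape_a=p.base**2 / sd**2,
            shape_b=sd**2 / p.base,
        )
    if p.family == "beta":
        m = p.base
        var = sd**2
        if var >= m * (1.0 - m):
            raise ValueError(
                f"{p.name}: beta moments infeasible (sd^2 >= mean*(1-mean))"
            )
        nu = m * (1.0 - m) / var - 1.0
        return Sampler(
            name=p.name, family="beta", mean=m, sd=sd, shape_a=m * nu, shape_b=(1.0 - m) * nu
        )
    raise ValueError(f"{p.name}: unknown family {p.family!r}")


def _traces(bundle: ParameterBundle, engine: str) -> tuple[MarkovTrace, MarkovTrace]:
    return tuple(
        build_trace(
            bundle.weibull[(arm, "PFS")],
            bundle.weibull[(arm, "OS")],
            bundle.settings,
            mode=engine,
            arm=arm,
        )
        for arm in ("combo", "chemo")
    )


def evaluate_model(
    bundle: ParameterBundle,
    overrides: Mapping[str, float] | None = None,
    engine: str = "transition",
    traces: tuple[MarkovTrace, MarkovTrace] | None = None,
    wtp: float | None = None,
):
    """One full deterministic model evaluation under parameter overrides.

    The state traces depend only on the survival parameters and horizon
    (never on costs, utilities, or the discount rate), so precomputed traces
    may be passed in when the model is re-run many times.
    """
    if traces is None:
        traces = _traces(bundle, engine)
    combo_trace, chemo_trace = traces
    combo_arm, chemo_arm = bundle.strategies(overrides)
    settings = bundle.settings_with(overrides)
    combo = accrue(combo_trace, combo_arm, settings)
    chemo = accrue(chemo_trace, chemo_arm, settings)
    return compute_icer(combo, chemo, wtp if wtp is not None else settings.wtp_per_qaly)


def run_owsa(
    bundle: ParameterBundle, settings: ModelSettings | None = None, engine: str = "transition"
) -> list[OWSARow]:
    """One-way sensitivity analysis over every parameter-table row.

    Returns rows sorted by tornado spread, largest first (ties broken
    alphabetically by parameter name).  ``downward_only`` rows vary over
    [low, base] only.
    """
    del settings  # horizon/discount come from the bundle; kept for symmetry
    traces = _traces(bundle, engine)
    rows = []
    for p in bundle.distributions:
        lo, hi = p.low, p.high
        if p.direction == "downward_only":
            hi = p.base
        icer_lo = evaluate_model(bundle, {p.name: lo}, traces=traces).icer
        icer_hi = evaluate_model(bundle, {p.name: hi}, traces=traces).icer
        rows.append(
            OWSARow(
                name=p.name, low_input=lo, high_input=hi, icer_low=icer_lo, icer_high=icer_hi
            )
        )
    return sorted(rows, key=lambda r: (-r.spread, r.name))


def run_psa(
    bundle: ParameterBundle,
    n_draws: int | None = None,
    seed: int = 0,
    engine: str = "transition",
    range_z: float = RANGE_Z,
) -> list[PSASample]:
    """Probabilistic sensitivity analysis.

    Draws ``n_draws`` joint parameter vectors (default: the configured
    ``psa_draws``) with a dedicated generator seeded by ``seed``, re-runs
    the deterministic model for each, and records the incremental cost and
    QALYs.  Sampled values are shared between arms where the parameter is
    shared (utilities, drug prices); draws that fail model evaluation are
    excluded and counted in the log.
    """
    if n_draws is None:
        n_draws = bundle.settings.psa_draws
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    sampled = [d for d in bundle.distributions if d.family != "fixed"]
    draws = {
        d.name: build_distribution(d, range_z=range_z).sample(rng, n_draws)
        for d in sampled
    }
    traces = _traces(bundle, engine)
    samples: list[PSASample] = []
    failures = 0
    for i in range(n_draws):
        values = {name: float(col[i]) for name, col in draws.items()}
        try:
            res = evaluate_model(bundle, values, traces=traces)
        except Exception:  # noqa: BLE001 - a bad draw must not kill the run
            failures += 1
            logger.exception("PSA draw %d failed; excluded", i)
            continue
        samples.append(
            PSASample(
                draw=i, values=values, delta_cost=res.delta_cost, delta_qalys=res.delta_qalys
            )
        )
    if failures:
        logger.warning("PSA: %d of %d draws failed and were excluded", failures, n_draws)
    return samples


def ceac(
    samples: Sequence[PSASample], wtp_grid: Sequence[float]
) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay value, the fraction of draws whose
    incremental net monetary benefit wtp * dQALY - dCost is nonnegative.
    """
    if len(samples) == 0:
        raise ValueError("ceac requires at least one PSA sample")
    if len(wtp_grid) == 0:
        raise ValueError("ceac requires a nonempty WTP grid")
    d_cost = np.array([s.delta_cost for s in samples])
    d_q = np.array([s.delta_qalys for s in samples])
    return [
        (float(w), float(np.mean(w * d_q - d_cost >= 0.0))) for w in wtp_grid
    ]


def owsa_frame(rows: Sequence[OWSARow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [r.name for r in rows],
            "low_input": [r.low_input for r in rows],
            "high_input": [r.high_input for r in rows],
            "icer_low": [r.icer_low for r in rows],
            "icer_high": [r.icer_high for r in rows],
            "spread": [r.spread for r in rows],
        }
    )


def psa_frame(samples: Sequence[PSASample]) -> pd.DataFrame:
    base = pd.DataFrame(
        {
            "draw": [s.draw for s in samples],
            "delta_cost": [s.delta_cost for s in samples],
            "delta_qalys": [s.delta_qalys for s in samples],
        }
    )
    values = pd.DataFrame([s.values for s in samples])
    return pd.concat([base, values], axis=1)
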