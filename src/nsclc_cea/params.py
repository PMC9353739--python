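"""Typed, validated model inputs and the canonical on-disk configuration.

All inputs of the cost-utility model live in a single YAML document with
three sections: global ``settings`` (cycle length, horizon, discounting,
willingness-to-pay), the fitted Weibull survival parameters per arm and
endpoint, and the cost/utility/discount parameter table with low/high
ranges and sampling families for sensitivity analysis.  The packaged
default configuration encodes the published base case; :func:`load_config`
with no argument returns it.

Monetary quantities are USD throughout.  Time is measured in 21-day model
cycles unless a function says otherwise.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "ConfigError",
    "WeibullParams",
    "ParamDistribution",
    "ModelSettings",
    "StrategySpec",
    "ParameterBundle",
    "load_config",
    "save_config",
    "export_csv",
    "bsa_stevenson",
    "DAYS_PER_YEAR",
    "DAYS_PER_MONTH",
]

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.4375

ARMS = ("combo", "chemo")
ENDPOINTS = ("PFS", "OS")


class ConfigError(ValueError):
    """A configuration value violates an invariant; the message names the field."""


@dataclass(frozen=True)
class WeibullParams:
    """Weibull survival curve S(t) = exp(-scale * t^shape), t in model cycles."""

    scale: float
    shape: float
    endpoint: str = "PFS"
    arm: str = "combo"

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ConfigError(f"WeibullParams.scale must be > 0, got {self.scale}")
        if not self.shape > 0:
            raise ConfigError(f"WeibullParams.shape must be > 0, got {self.shape}")
        if self.endpoint not in ENDPOINTS:
            raise ConfigError(f"WeibullParams.endpoint must be one of {ENDPOINTS}")
        if self.arm not in ARMS:
            raise ConfigError(f"WeibullParams.arm must be one of {ARMS}")


@dataclass(frozen=True)
class ParamDistribution:
    """One row of the sensitivity-analysis parameter table.

    ``base`` is the deterministic value, ``[low, high]`` the one-way range,
    and ``family`` the probabilistic sampling family (``gamma`` for costs,
    ``beta`` for utilities, ``fixed`` for point masses).  ``direction``
    ``downward_only`` marks a price that cannot rise (high == base); its
    one-way interval is [low, base].
    """

    name: str
    base: float
    low: float
    high: float
    family: str = "gamma"
    direction: str = "two_sided"

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "beta", "fixed"):
            raise ConfigError(f"{self.name}: unknown family {self.family!r}")
        if self.direction not in ("two_sided", "downward_only"):
            raise ConfigError(f"{self.name}: unknown direction {self.direction!r}")
        if not (self.low <= self.base <= self.high):
            raise ConfigError(
                f"{self.name}: requires low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )
        if self.family == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            raise ConfigError(f"{self.name}: beta parameters must lie in [0, 1]")
        if self.direction == "downward_only" and self.high != self.base:
            raise ConfigError(f"{self.name}: downward_only requires high == base")


@dataclass(frozen=True)
class ModelSettings:
    """Global model constants: time grid, discounting, thresholds."""

    cycle_length_days: float = 21.0
    horizon_cycles: int = 174  # ceil(10 * 365.25 / 21)
    annual_discount_rate: float = 0.05
    background_annual_mortality: float = 0.0071
    wtp_per_qaly: float = 31510.57
    psa_draws: int = 1000
    cny_per_usd_2020: float = 6.8974  # provenance only

    def __post_init__(self) -> None:
        if self.horizon_cycles < 1:
            raise ConfigError("ModelSettings.horizon_cycles must be >= 1")
        if not (0.0 <= self.annual_discount_rate <= 1.0):
            raise ConfigError("ModelSettings.annual_discount_rate must be in [0, 1]")
        if not (0.0 <= self.background_annual_mortality < 1.0):
            raise ConfigError("ModelSettings.background_annual_mortality must be in [0, 1)")
        if self.wtp_per_qaly <= 0:
            raise ConfigError("ModelSettings.wtp_per_qaly must be > 0")
        if self.psa_draws < 1:
            raise ConfigError("ModelSettings.psa_draws must be >= 1")

    @property
    def cycles_per_year(self) -> float:
        return DAYS_PER_YEAR / self.cycle_length_days


@dataclass(frozen=True)
class StrategySpec:
    """One treatment arm's complete resolved cost and utility schedule.

    Phase structure: ``induction_cycles`` of platinum-doublet (+ camrelizumab
    in the combo arm), then pemetrexed maintenance; camrelizumab stops after
    ``camrelizumab_max_cycles`` (None in the chemotherapy arm).  Disease
    management switches from the early to the late tariff after
    ``dm_breakpoint`` model cycles regardless of state.  The progressed-disease
    state accrues ``second_line_cost_per_cycle``; the adverse-event management
    cost is a one-off lump at cycle 1.
    """

    name: str
    induction_cycles: int = 4
    camrelizumab_max_cycles: int | None = 34
    camrelizumab_cost: float = 0.0
    pemetrexed_cost: float = 0.0
    carboplatin_cost: float = 0.0
    pretreatment_cost: float = 0.0
    admin_induction: float = 0.0
    admin_maintenance: float = 0.0
    admin_post_cap: float = 0.0
    dm_early: float = 0.0
    dm_late: float = 0.0
    dm_breakpoint: int = 18
    second_line_cost_per_cycle: float = 0.0
    ae_lump_cost: float = 0.0
    utility_pfs: float = 0.804
    utility_pd: float = 0.321

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.type in ("float", float) and isinstance(v, (int, float)) and v < 0:
                raise ConfigError(f"StrategySpec.{f.name} must be >= 0, got {v}")
        if self.camrelizumab_max_cycles is not None:
            if not self.induction_cycles < self.camrelizumab_max_cycles:
                raise ConfigError(
                    f"StrategySpec.{self.name}: induction_cycles must be < "
                    "camrelizumab_max_cycles"
                )
        for u in ("utility_pfs", "utility_pd"):
            if not (0.0 <= getattr(self, u) <= 1.0):
                raise ConfigError(f"StrategySpec.{u} must lie in [0, 1]")


@dataclass(frozen=True)
class ParameterBundle:
    """The full validated input set: settings, survival curves, parameter table."""

    settings: ModelSettings
    weibull: Mapping[tuple[str, str], WeibullParams]
    distributions: Sequence[ParamDistribution]
    induction_cycles: int = 4
    camrelizumab_max_cycles: int = 34
    dm_breakpoint: int = 18

    def __post_init__(self) -> None:
        for arm in ARMS:
            for ep in ENDPOINTS:
                if (arm, ep) not in self.weibull:
                    raise ConfigError(f"missing Weibull parameters for ({arm}, {ep})")
        names = [d.name for d in self.distributions]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate parameter names in distributions")

    def distribution(self, name: str) -> ParamDistribution:
        for d in self.distributions:
            if d.name == name:
                return d
        raise KeyError(name)

    def value(self, name: str, overrides: Mapping[str, float] | None = None) -> float:
        if overrides and name in overrides:
            return float(overrides[name])
        return self.distribution(name).base

    def settings_with(
        self, overrides: Mapping[str, float] | None = None
    ) -> ModelSettings:
        """Settings with any ``discount_rate`` override applied."""
        rate = self.value("discount_rate", overrides)
        if rate != self.settings.annual_discount_rate:
            return replace(self.settings, annual_discount_rate=rate)
        return self.settings

    def strategies(
        self, overrides: Mapping[str, float] | None = None
    ) -> tuple[StrategySpec, StrategySpec]:
        """Resolve the two arms' cost schedules from the parameter table.

        The progressed-disease state of either arm accrues both second-line
        components (docetaxel chemotherapy plus immunotherapy); this joint
        costing is what reproduces the published base-case totals (see the
        methods note).
        """
        v = lambda n: self.value(n, overrides)  # noqa: E731
        second_line = v("cost_second_line_combo_arm") + v("cost_second_line_chemo_arm")
        common = dict(
            induction_cycles=self.induction_cycles,
            pemetrexed_cost=v("cost_pemetrexed"),
            carboplatin_cost=v("cost_carboplatin"),
            pretreatment_cost=v("cost_pretreatment"),
            dm_early=v("cost_disease_mgmt_first18"),
            dm_late=v("cost_disease_mgmt_after18"),
            dm_breakpoint=self.dm_breakpoint,
            second_line_cost_per_cycle=second_line,
            utility_pfs=v("utility_pfs"),
            utility_pd=v("utility_pd"),
        )
        combo = StrategySpec(
            name="combo",
            camrelizumab_max_cycles=self.camrelizumab_max_cycles,
            camrelizumab_cost=v("cost_camrelizumab"),
            admin_induction=v("cost_admin_combo_le4"),
            admin_maintenance=v("cost_admin_combo_5_34"),
            admin_post_cap=v("cost_admin_combo_gt34"),
            ae_lump_cost=v("cost_ae_combo"),
            **common,
        )
        chemo = StrategySpec(
            name="chemo",
            camrelizumab_max_cycles=None,
            camrelizumab_cost=0.0,
            admin_induction=v("cost_admin_chemo_le4"),
            admin_maintenance=v("cost_admin_chemo_gt4"),
            admin_post_cap=v("cost_admin_chemo_gt4"),
            ae_lump_cost=v("cost_ae_chemo"),
            **common,
        )
        return combo, chemo


def _require(mapping: Mapping, key: str, context: str):
    if key not in mapping:
        raise ConfigError(f"missing key {key!r} in {context}")
    return mapping[key]


def load_config(path: str | Path | None = None) -> ParameterBundle:
    """Load and validate a model configuration.

    With ``path=None`` the packaged default (the published base case) is
    returned.  Raises :class:`ConfigError` naming the offending field on any
    violated invariant.
    """
    if path is None:
        source = importlib.resources.files("nsclc_cea").joinpath(
            "data/default_config.yaml"
        )
        raw = yaml.safe_load(source.read_text())
    else:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    s = _require(raw, "settings", "config")
    settings = ModelSettings(
        cycle_length_days=float(_require(s, "cycle_length_days", "settings")),
        horizon_cycles=int(_require(s, "horizon_cycles", "settings")),
        annual_discount_rate=float(_require(s, "annual_discount_rate", "settings")),
        background_annual_mortality=float(
            _require(s, "background_annual_mortality", "settings")
        ),
        wtp_per_qaly=float(_require(s, "wtp_per_qaly", "settings")),
        psa_draws=int(s.get("psa_draws", 1000)),
        cny_per_usd_2020=float(s.get("cny_per_usd_2020", 6.8974)),
    )

    w = _require(raw, "weibull", "config")
    weibull: dict[tuple[str, str], WeibullParams] = {}
    for arm in ARMS:
        arm_block = _require(w, arm, "weibull")
        for ep in ENDPOINTS:
            row = _require(arm_block, ep, f"weibull.{arm}")
            weibull[(arm, ep)] = WeibullParams(
                scale=float(_require(row, "scale", f"weibull.{arm}.{ep}")),
                shape=float(_require(row, "shape", f"weibull.{arm}.{ep}")),
                endpoint=ep,
                arm=arm,
            )

    dists = [
        ParamDistribution(
            name=str(_require(row, "name", "parameters")),
            base=float(_require(row, "base", "parameters")),
            low=float(_require(row, "low", "parameters")),
            high=float(_require(row, "high", "parameters")),
            family=str(row.get("family", "gamma")),
            direction=str(row.get("direction", "two_sided")),
        )
        for row in _require(raw, "parameters", "config")
    ]

    structure = raw.get("structure", {})
    bundle = ParameterBundle(
        settings=settings,
        weibull=weibull,
        distributions=tuple(dists),
        induction_cycles=int(structure.get("induction_cycles", 4)),
        camrelizumab_max_cycles=int(structure.get("camrelizumab_max_cycles", 34)),
        dm_breakpoint=int(structure.get("disease_mgmt_breakpoint_cycle", 18)),
    )
    # building the strategies exercises the cross-field invariants
    bundle.strategies()
    return bundle


def save_config(bundle: ParameterBundle, path: str | Path) -> None:
    """Write a bundle back to the canonical YAML dialect (round-trip safe)."""
    s = bundle.settings
    doc = {
        "settings": {
            "cycle_length_days": s.cycle_length_days,
            "horizon_cycles": s.horizon_cycles,
            "annual_discount_rate": s.annual_discount_rate,
            "background_annual_mortality": s.background_annual_mortality,
            "wtp_per_qaly": s.wtp_per_qaly,
            "psa_draws": s.psa_draws,
            "cny_per_usd_2020": s.cny_per_usd_2020,
        },
        "weibull": {
            arm: {
                ep: {
                    "scale": bundle.weibull[(arm, ep)].scale,
                    "shape": bundle.weibull[(arm, ep)].shape,
                }
                for ep in ENDPOINTS
            }
            for arm in ARMS
        },
        "structure": {
            "induction_cycles": bundle.induction_cycles,
            "camrelizumab_max_cycles": bundle.camrelizumab_max_cycles,
            "disease_mgmt_breakpoint_cycle": bundle.dm_breakpoint,
        },
        "parameters": [
            {
                "name": d.name,
                "base": d.base,
                "low": d.low,
                "high": d.high,
                "family": d.family,
                "direction": d.direction,
            }
            for d in bundle.distributions
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def export_csv(bundle: ParameterBundle, path: str | Path) -> pd.DataFrame:
    """Audit export: the full loaded parameter table as CSV."""
    rows = [
        {
            "section": "weibull",
            "name": f"{arm}_{ep}_{fieldname}",
            "base": getattr(bundle.weibull[(arm, ep)], fieldname),
            "low": "",
            "high": "",
            "family": "",
            "direction": "",
        }
        for arm in ARMS
        for ep in ENDPOINTS
        for fieldname in ("scale", "shape")
    ]
    rows += [
        {
            "section": "parameter",
            "name": d.name,
            "base": d.base,
            "low": d.low,
            "high": d.high,
            "family": d.family,
            "direction": d.direction,
        }
        for d in bundle.distributions
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def bsa_stevenson(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2) by the Stevenson (Xu Wensheng) formula.

    BSA = 0.0061 * height + 0.0128 * weight - 0.1529.  Used only to document
    the provenance of the per-cycle drug doses (the cohort average is
    1.71 m^2); the cost table already prints per-cycle totals.
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return 0.0061 * height_cm + 0.0128 * weight_kg - 0.1529
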