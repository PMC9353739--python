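"""Synthetic trial-like inputs for exercising the full pipeline.

The survival inputs of the analysis are digitized Kaplan-Meier coordinates;
no patient-level data are published.  This module generates the statistical
stand-ins: pseudo individual-patient data (IPD) drawn from known Weibull
truths with independent exponential censoring, product-limit curves
estimated from them, and a digitization-noise model that subsamples and
jitters a curve the way manual curve extraction does.  A fixture of the
printed grade >=3 treatment-related adverse-event incidences is included
for the expected-cost helper.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .params import WeibullParams
from .survival import KMCurve

__all__ = [
    "simulate_ipd",
    "km_from_ipd",
    "digitize_noise",
    "write_km_csv",
    "trae_fixture",
    "SEVERE_TRAE_COUNTS",
]

# grade >=3 treatment-related adverse events with incidence > 3% in either
# arm (event, combination-arm rate, chemotherapy-arm rate); the "<1%"
# chemotherapy gamma-glutamyltransferase entry is stored as its count, 1/207
_TRAE_ROWS = [
    ("Neutrophil count decreased", 0.38, 0.30),
    ("White blood cell count decreased", 0.20, 0.14),
    ("Anemia", 0.19, 0.11),
    ("Platelet count decreased", 0.17, 0.12),
    ("Lymphocyte count decreased", 0.04, 0.02),
    ("Alanine aminotransferase increased", 0.05, 0.02),
    ("Asthenia", 0.03, 0.01),
    ("Gamma-glutamyltransferase increased", 0.03, 1.0 / 207.0),
]

# any-event severe TRAE counts per arm: (events, patients)
SEVERE_TRAE_COUNTS = {"combo": (74, 205), "chemo": (27, 207)}


def simulate_ipd(
    params: WeibullParams,
    n: int,
    censor_annual_rate: float = 0.12,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pseudo-IPD: n (time, event) records from a Weibull truth.

    Event times by inverse transform of S(t) = exp(-scale * t^shape);
    censoring times independent exponential with the given annual rate
    (converted to the cycle scale).  The default censoring rate is chosen
    so roughly a fifth of chemotherapy-arm overall-survival records censor
    within the trial's first year of extended follow-up (~52 cycles).
    Returns a DataFrame with columns ``time`` (cycles) and ``event``
    (True = observed death/progression, False = censored).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if censor_annual_rate < 0:
        raise ValueError("censor_annual_rate must be >= 0")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    event_times = (-np.log(u) / params.scale) ** (1.0 / params.shape)
    if censor_annual_rate > 0:
        rate_per_cycle = censor_annual_rate * 21.0 / 365.25
        censor_times = rng.exponential(1.0 / rate_per_cycle, size=n)
    else:
        censor_times = np.full(n, np.inf)
    time = np.minimum(event_times, censor_times)
    event = event_times <= censor_times
    return pd.DataFrame({"time": time, "event": event})


def km_from_ipd(ipd: pd.DataFrame) -> KMCurve:
    """Product-limit (Kaplan-Meier) curve from pseudo-IPD.

    Coordinates are taken at the observed event times; a leading point at
    time 0 with survival 1 is included.  Survival-zero points (everyone
    dead) are dropped because digitized coordinates live in (0, 1].
    """
    if len(ipd) == 0:
        raise ValueError("ipd must contain at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd["time"], event_observed=ipd["event"])
    sf = kmf.survival_function_.iloc[:, 0]
    times = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    keep = surv > 0.0
    return KMCurve(times=times[keep], survival=surv[keep])


def digitize_noise(
    curve: KMCurve,
    jitter_sd: float,
    n_points: int,
    seed: int | None = None,
) -> KMCurve:
    """Emulate manual curve-extraction error.

    Subsamples the curve to ``n_points`` evenly spaced coordinates, adds
    Gaussian jitter to the survival values, then re-imposes monotonicity
    (running minimum) and the (0, 1] range.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    n_points = min(n_points, curve.n_points)
    idx = np.unique(np.linspace(0, curve.n_points - 1, n_points).round().astype(int))
    times = curve.times[idx]
    surv = curve.survival[idx].copy()
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        surv = surv + rng.normal(0.0, jitter_sd, size=surv.size)
    surv = np.clip(surv, 1e-6, 1.0)
    surv = np.minimum.accumulate(surv)
    return KMCurve(times=times, survival=surv)


def write_km_csv(curve: KMCurve, path: str | Path) -> None:
    """Write a curve in the two-column dialect ``survival.read_km_csv`` reads
    (time in cycles)."""
    pd.DataFrame({"time": curve.times, "survival": curve.survival}).to_csv(
        path, index=False
    )


def trae_fixture() -> pd.DataFrame:
    """Grade >=3 treatment-related adverse-event incidences per arm."""
    df = pd.DataFrame(_TRAE_ROWS, columns=["event", "combo_rate", "chemo_rate"])
    return df
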