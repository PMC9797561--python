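"""Synthetic fixtures: analytic twitches, calibration ranges, cohorts.

Everything the test suite needs is generated here from closed forms and
seeded random draws, standing in for experimental recordings (which are not
distributed with the package):

* two-exponential twitch-like traces whose peak time and amplitude have
  closed forms, giving exact oracles for biomarker extraction;
* calibration ranges derived from percentiles of a simulated control
  population, standing in for experimentally derived physiological ranges;
* grouped Gaussian biomarker cohorts with known effect sizes, exercising
  the statistics layer.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .population import CalibrationRanges, PopulationTable
from .simulate import Trace

__all__ = ["synth_twitch", "twitch_peak_time", "synth_calibration_ranges",
           "synth_cohort"]


def twitch_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Analytic peak time of the two-exponential twitch, ms."""
    return math.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)


def synth_twitch(
    amp: float,
    tau_rise: float,
    tau_decay: float,
    baseline: float = 0.0,
    cycle: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    dt: float = 1.0,
    channel: str = "tension",
) -> Trace:
    """Two-exponential twitch x(t) = baseline + amp*(e^(-t/τd) - e^(-t/τr))/norm.

    The normaliser makes the noise-free peak exactly ``amp`` above baseline,
    at the closed-form peak time (recorded in ``trace.meta`` as ground
    truth).  Gaussian noise of SD ``noise_sd`` is added pointwise, seeded.
    The waveform is written to the requested channel ("tension" or "cai");
    the other channel is held flat at its baseline.
    """
    if tau_rise >= tau_decay:
        raise ValueError("tau_rise must be smaller than tau_decay")
    if amp <= 0:
        raise ValueError("amp must be positive")
    t = np.arange(0.0, cycle + dt / 2, dt)
    t_peak = twitch_peak_time(tau_rise, tau_decay)
    norm = math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)
    x = baseline + amp * (np.exp(-t / tau_decay) - np.exp(-t / tau_rise)) / norm
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=x.size)
    flat = np.full_like(t, baseline)
    meta = {"amp": amp, "t_peak": t_peak, "tau_rise": tau_rise,
            "tau_decay": tau_decay, "baseline": baseline, "channel": channel,
            "noise_sd": noise_sd, "seed": seed}
    if channel == "tension":
        return Trace(time=t, cai=flat, tension=x, cycle_ms=cycle, meta=meta)
    if channel == "cai":
        return Trace(time=t, cai=x, tension=flat, cycle_ms=cycle, meta=meta)
    raise ValueError("channel must be 'tension' or 'cai'")


def synth_calibration_ranges(
    control_population: PopulationTable,
    lo_pct: float = 2.5,
    hi_pct: float = 97.5,
    biomarkers=("tension_amp", "tension_rt50", "tension_rt90",
                "ca_amp", "ca_td50", "ca_td95"),
) -> CalibrationRanges:
    """Percentile-based acceptance windows from a simulated control population.

    Stands in for experimentally derived physiological ranges: each listed
    biomarker's window is [percentile(lo_pct), percentile(hi_pct)] of the
    control-population values.
    """
    if not 0 <= lo_pct <= hi_pct <= 100:
        raise ValueError("need 0 <= lo_pct <= hi_pct <= 100")
    bm = control_population.biomarkers.get("control")
    if bm is None or bm.empty:
        raise ValueError("population has no control biomarkers")
    ranges = {}
    for name in biomarkers:
        vals = bm[name].dropna()
        if vals.empty:
            raise ValueError(f"no defined values for biomarker {name!r}")
        ranges[name] = (float(np.percentile(vals, lo_pct)),
                        float(np.percentile(vals, hi_pct)))
    return CalibrationRanges(ranges)


def synth_cohort(
    n_per_group: int,
    effect_sizes,
    noise_sd: float = 1.0,
    seed: int | None = 0,
    base_mean: float = 0.0,
) -> pd.DataFrame:
    """Gaussian biomarker cohorts with specified mean shifts.

    ``effect_sizes`` gives, per group, the mean shift from ``base_mean`` in
    the same units as ``noise_sd``.  Returns a tidy frame with columns
    ``group`` and ``value``; identical for identical seeds.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 observations per group")
    rng = np.random.default_rng(seed)
    frames = []
    for gi, shift in enumerate(effect_sizes):
        vals = rng.normal(base_mean + shift, noise_sd, size=n_per_group)
        frames.append(pd.DataFrame({"group": f"group{gi}", "value": vals}))
    return pd.concat(frames, ignore_index=True)
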