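"""Twitch and calcium-transient biomarker extraction.

Conventions (one set per channel):

* baseline      -- pre-stimulus value of the analysed beat,
* amplitude     -- peak minus baseline,
* time to peak  -- time from the stimulus to the transient maximum,
* RT50 / RT90   -- time from the peak to 50% / 90% decay of the amplitude,
  with threshold crossings linearly interpolated between samples,
* TD50 / TD95   -- time from the stimulus to the 50% / 95% decay crossing
  (calcium only; these are the transient-duration calibration metrics),
* diastolic     -- the baseline value itself.

Relaxation metrics of flat transients (amplitude below a configurable
floor), or of transients whose decay does not reach the threshold inside the
analysed window (e.g. tension nearly suppressed by a high myosin-inhibitor
dose), are reported as NaN and flagged undefined rather than fabricated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np

from .simulate import Trace

__all__ = ["BiomarkerSet", "extract_biomarkers", "BIOMARKER_NAMES"]

#: amplitude floor below which a channel is treated as flat
AMPLITUDE_FLOOR = 1e-9


@dataclass
class BiomarkerSet:
    """Per-beat biomarkers for tension (kPa, ms) and calcium (µM, ms)."""

    tension_amp: float = math.nan
    tension_ttp: float = math.nan
    tension_rt50: float = math.nan
    tension_rt90: float = math.nan
    tension_dia: float = math.nan
    ca_amp: float = math.nan
    ca_ttp: float = math.nan
    ca_rt50: float = math.nan
    ca_rt90: float = math.nan
    ca_td50: float = math.nan
    ca_td95: float = math.nan
    ca_dia: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def is_defined(self, name: str) -> bool:
        return not math.isnan(getattr(self, name))


BIOMARKER_NAMES = tuple(f.name for f in fields(BiomarkerSet))


def _crossing_time(t: np.ndarray, x: np.ndarray, start: int, level: float) -> float:
    """First linearly interpolated downward crossing of ``level`` at or after
    index ``start``; NaN if the trace never reaches it."""
    below = np.nonzero(x[start:] <= level)[0]
    if below.size == 0:
        return math.nan
    j = start + below[0]
    if j == start or x[j] == level or x[j - 1] == x[j]:
        return t[j]
    frac = (x[j - 1] - level) / (x[j - 1] - x[j])
    return t[j - 1] + frac * (t[j] - t[j - 1])


def _channel_metrics(
    t: np.ndarray, x: np.ndarray, amplitude_floor: float
) -> dict[str, float]:
    baseline = x[0]
    peak_idx = int(np.argmax(x))
    peak = x[peak_idx]
    t_peak = t[peak_idx]
    if 0 < peak_idx < len(x) - 1:
        # parabolic sub-sample refinement of the peak position and height
        y0, y1, y2 = x[peak_idx - 1], x[peak_idx], x[peak_idx + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            shift = 0.5 * (y0 - y2) / denom
            if abs(shift) <= 1.0:
                t_peak = t[peak_idx] + shift * (t[peak_idx + 1] - t[peak_idx])
                peak = y1 - 0.25 * (y0 - y2) * shift
    amp = peak - baseline
    out = {"dia": baseline, "amp": max(amp, 0.0)}
    if amp < amplitude_floor:
        out.update(amp=0.0, ttp=math.nan, rt50=math.nan, rt90=math.nan,
                   td50=math.nan, td95=math.nan)
        return out
    # tie-break for noisy plateaus: first sample reaching peak - eps
    eps = 1e-3 * amp
    first_at_peak = int(np.nonzero(x >= x[peak_idx] - eps)[0][0])
    out["ttp"] = t_peak - t[0]
    start = first_at_peak
    for key, frac in (("rt50", 0.5), ("rt90", 0.9), ("td50", 0.5), ("td95", 0.95)):
        level = peak - frac * amp
        tc = _crossing_time(t, x, start, level)
        if math.isnan(tc):
            warnings.warn(
                f"decay to {int(frac * 100)}% not reached inside the analysed "
                "window; relaxation metric undefined", RuntimeWarning, stacklevel=3)
            out[key] = math.nan
        elif key.startswith("rt"):
            out[key] = tc - t_peak
        else:
            out[key] = tc - t[0]
    return out


def extract_biomarkers(
    trace: Trace,
    beat_window: int | None = None,
    amplitude_floor: float = AMPLITUDE_FLOOR,
) -> BiomarkerSet:
    """Extract biomarkers from one beat of a trace.

    ``beat_window`` selects the beat (default: the last one); the beat's
    first sample is taken as the stimulus instant and pre-stimulus baseline.
    """
    beat = trace.beat(-1 if beat_window is None else beat_window)
    if len(beat.time) < 3:
        raise ValueError("trace must contain at least one resolvable beat")
    tn = _channel_metrics(beat.time, beat.tension, amplitude_floor)
    ca = _channel_metrics(beat.time, beat.cai, amplitude_floor)
    return BiomarkerSet(
        tension_amp=tn["amp"], tension_ttp=tn.get("ttp", math.nan),
        tension_rt50=tn.get("rt50", math.nan), tension_rt90=tn.get("rt90", math.nan),
        tension_dia=tn["dia"],
        ca_amp=ca["amp"], ca_ttp=ca.get("ttp", math.nan),
        ca_rt50=ca.get("rt50", math.nan), ca_rt90=ca.get("rt90", math.nan),
        ca_td50=ca.get("td50", math.nan), ca_td95=ca.get("td95", math.nan),
        ca_dia=ca["dia"],
    )
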