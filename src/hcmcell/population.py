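"""Populations of in-silico cardiomyocytes.

The population-of-models workflow: sample per-model multiplicative scaling
vectors with Latin Hypercube Sampling over [50-200]% of baseline, simulate
every model to its paced steady state, accept the models whose twitch and
calcium-transient biomarkers fall inside physiological calibration ranges,
and re-run the accepted (calibrated) population under genotype or drug
remodellings to compare biomarker distributions between scenarios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import qmc

from .biomarkers import BIOMARKER_NAMES, extract_biomarkers
from .params import CellParams, default_params
from .scenarios import ScalingSpec
from .simulate import run_population_steady_state, run_to_steady_state

__all__ = [
    "DEFAULT_AXES", "CalibrationRanges", "PopulationTable",
    "lhs_sample", "simulate_population", "calibrate_population",
    "apply_calibration", "build_control_population", "run_population",
]

#: default sampled parameter axes: the calcium-handling and myofilament
#: subset of the population variability axes (release flux, SERCA uptake and
#: affinity, extrusion, myofilament calcium sensitivity, crossbridge cycling
#: rates, troponin buffer capacity)
DEFAULT_AXES = (
    "g_amp", "V_serca", "K_serca", "k_ncx", "Ca50", "k_uw", "k_ws", "TRPN_tot",
)

#: sampling range as fraction of baseline ([50-200]%)
DEFAULT_RANGE = (0.5, 2.0)

#: steady-state settings for population work (documented numerical choice;
#: biomarkers change by < 0.1% versus the tighter single-cell default)
POP_SS_TOL = 1e-4
POP_MAX_BEATS = 500


@dataclass(frozen=True)
class CalibrationRanges:
    """Per-biomarker acceptance windows, in each biomarker's units."""

    ranges: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if name not in BIOMARKER_NAMES:
                raise KeyError(f"unknown biomarker {name!r}")
            if lo > hi:
                raise ValueError(f"range for {name!r} has min > max")

    def __iter__(self):
        return iter(self.ranges.items())

    def to_yaml(self, path: str | Path) -> None:
        data = {k: [float(lo), float(hi)] for k, (lo, hi) in self.ranges.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CalibrationRanges":
        data = yaml.safe_load(Path(path).read_text())
        return cls({k: (float(v[0]), float(v[1])) for k, v in data.items()})


@dataclass
class PopulationTable:
    """Per-model scaling vectors, acceptance flags, and scenario biomarkers.

    ``scales`` has one row per model (index ``model_id``) and one column per
    sampled parameter.  ``biomarkers`` maps scenario name -> DataFrame of
    biomarker values aligned on ``model_id``.  ``states`` caches final ODE
    states per scenario for warm-starting follow-up runs (not serialised).
    """

    scales: pd.DataFrame
    accepted: pd.Series | None = None
    biomarkers: dict[str, pd.DataFrame] = field(default_factory=dict)
    states: dict[str, np.ndarray] = field(default_factory=dict)
    rejection_tallies: pd.Series | None = None
    seed: int | None = None

    @property
    def n_models(self) -> int:
        return len(self.scales)

    @property
    def n_accepted(self) -> int:
        return 0 if self.accepted is None else int(self.accepted.sum())

    def accepted_ids(self) -> pd.Index:
        if self.accepted is None:
            raise ValueError("population has not been calibrated yet")
        return self.scales.index[self.accepted]

    def model_params(self, model_id: int, base: CellParams) -> CellParams:
        return base.scaled(self.scales.loc[model_id].to_dict())

    def to_csv(self, path: str | Path) -> None:
        out = self.scales.copy()
        if self.accepted is not None:
            out["accepted"] = self.accepted
        for scen, bm in sorted(self.biomarkers.items()):
            for col in bm.columns:
                out[f"{scen}__{col}"] = bm[col]
        out.to_csv(path, index_label="model_id", float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PopulationTable":
        df = pd.read_csv(path, index_col="model_id")
        scale_cols = [c for c in df.columns if "__" not in c and c != "accepted"]
        biom: dict[str, pd.DataFrame] = {}
        for col in df.columns:
            if "__" in col:
                scen, name = col.split("__", 1)
                biom.setdefault(scen, pd.DataFrame(index=df.index))[name] = df[col]
        accepted = df["accepted"].astype(bool) if "accepted" in df else None
        return cls(scales=df[scale_cols], accepted=accepted, biomarkers=biom)


def lhs_sample(
    n: int,
    param_names: Sequence[str] = DEFAULT_AXES,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    seed: int | None = 0,
) -> PopulationTable:
    """Latin-Hypercube sample of per-model scaling factors.

    Each parameter's range (default [0.5, 2.0] of baseline) is divided into
    ``n`` equal-width strata with exactly one sample in each; reproducible
    for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = list(param_names)
    lo = np.empty(len(names))
    hi = np.empty(len(names))
    for j, name in enumerate(names):
        lo[j], hi[j] = (ranges or {}).get(name, DEFAULT_RANGE)
        if not lo[j] < hi[j]:
            raise ValueError(f"invalid range for {name!r}: need lo < hi")
    unit = qmc.LatinHypercube(d=len(names), seed=seed).random(n)
    sample = qmc.scale(unit, lo, hi)
    scales = pd.DataFrame(sample, columns=names)
    scales.index.name = "model_id"
    return PopulationTable(scales=scales, seed=seed)


def _params_list(
    table: PopulationTable, base: CellParams, spec: ScalingSpec | None,
    ids: pd.Index,
) -> list[CellParams]:
    out = []
    for mid in ids:
        p = base.scaled(table.scales.loc[mid].to_dict())
        if spec is not None:
            p = spec.apply(p)
        out.append(p)
    return out


def simulate_population(
    table: PopulationTable,
    base: CellParams | None = None,
    spec: ScalingSpec | None = None,
    ids: pd.Index | None = None,
    y0: np.ndarray | None = None,
    ss_tol: float = POP_SS_TOL,
    max_beats: int = POP_MAX_BEATS,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Run models to steady state; return (biomarkers, final states, converged)."""
    base = default_params() if base is None else base
    ids = table.scales.index if ids is None else ids
    plist = _params_list(table, base, spec, ids)
    if y0 is None:
        # warm-start the whole batch from the baseline steady state
        y0 = run_to_steady_state(base, tol=ss_tol, max_beats=max_beats).state
    states, traces, _, converged = run_population_steady_state(
        plist, tol=ss_tol, max_beats=max_beats, y0=y0
    )
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # truncated decays -> NaN
        for tr in traces:
            rows.append(extract_biomarkers(tr).as_dict())
    bm = pd.DataFrame(rows, index=ids)
    bm.index.name = "model_id"
    return bm, states, converged


def calibrate_population(
    table: PopulationTable,
    ranges: CalibrationRanges,
    base: CellParams | None = None,
    ss_tol: float = POP_SS_TOL,
    max_beats: int = POP_MAX_BEATS,
) -> PopulationTable:
    """Simulate every model at baseline and accept those whose calibrated
    biomarkers all lie inside their ranges.

    Models that fail to converge are rejected.  Returns the same table with
    ``accepted`` flags, control biomarkers, and per-biomarker rejection
    tallies filled in.
    """
    base = default_params() if base is None else base
    bm, states, converged = simulate_population(
        table, base, spec=None, ss_tol=ss_tol, max_beats=max_beats)
    accepted = pd.Series(converged, index=bm.index)
    tallies = {}
    for name, (lo, hi) in ranges:
        vals = bm[name]
        ok = (vals >= lo) & (vals <= hi) & np.isfinite(vals)
        tallies[name] = int((~ok).sum())
        accepted &= ok
    table.accepted = accepted
    table.biomarkers["control"] = bm
    table.states["control"] = states
    table.rejection_tallies = pd.Series(tallies)
    if accepted.sum() == 0:
        warnings.warn("calibration accepted no models", RuntimeWarning, stacklevel=2)
    return table


def apply_calibration(table: PopulationTable, ranges: CalibrationRanges) -> PopulationTable:
    """Set acceptance flags from already-computed control biomarkers."""
    bm = table.biomarkers.get("control")
    if bm is None:
        raise ValueError("population has no control biomarkers; simulate first")
    accepted = pd.Series(True, index=bm.index)
    tallies = {}
    for name, (lo, hi) in ranges:
        vals = bm[name]
        ok = (vals >= lo) & (vals <= hi) & np.isfinite(vals)
        tallies[name] = int((~ok).sum())
        accepted &= ok
    table.accepted = accepted
    table.rejection_tallies = pd.Series(tallies)
    if accepted.sum() == 0:
        warnings.warn("calibration accepted no models", RuntimeWarning, stacklevel=2)
    return table


def build_control_population(
    n: int,
    seed: int = 0,
    base: CellParams | None = None,
    lo_pct: float = 2.5,
    hi_pct: float = 97.5,
    ss_tol: float = POP_SS_TOL,
    max_beats: int = POP_MAX_BEATS,
) -> tuple[PopulationTable, CalibrationRanges]:
    """Sample, simulate and calibrate a control population in one call.

    Calibration ranges are the [lo_pct, hi_pct] percentiles of the sampled
    control population's own biomarkers (the synthetic stand-in for
    experimentally derived physiological ranges).
    """
    from .synthetic import synth_calibration_ranges

    base = default_params() if base is None else base
    table = lhs_sample(n, seed=seed)
    bm, states, converged = simulate_population(
        table, base, ss_tol=ss_tol, max_beats=max_beats)
    table.biomarkers["control"] = bm
    table.states["control"] = states
    ranges = synth_calibration_ranges(table, lo_pct, hi_pct)
    apply_calibration(table, ranges)
    table.accepted &= pd.Series(converged, index=bm.index)
    return table, ranges


def run_population(
    table: PopulationTable,
    spec: ScalingSpec,
    base: CellParams | None = None,
    scenario_name: str | None = None,
    ss_tol: float = POP_SS_TOL,
    max_beats: int = POP_MAX_BEATS,
) -> PopulationTable:
    """Apply a scenario remodelling to the accepted population and attach its
    biomarkers under ``scenario_name`` (default: the spec's name).

    Models whose relaxation metrics are undefined in the scenario (e.g.
    suppressed twitches under high inhibitor doses) are retained with NaN
    metrics, not dropped.
    """
    if table.accepted is None or table.n_accepted == 0:
        raise ValueError("population must be calibrated with >= 1 accepted model")
    ids = table.accepted_ids()
    warm = table.states.get("control")
    y0 = None
    if warm is not None:
        pos = [table.scales.index.get_loc(i) for i in ids]
        y0 = warm[pos]
    bm, states, _ = simulate_population(
        table, base, spec=spec, ids=ids, y0=y0, ss_tol=ss_tol, max_beats=max_beats)
    name = scenario_name or spec.name
    table.biomarkers[name] = bm
    table.states[name] = states
    return table
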