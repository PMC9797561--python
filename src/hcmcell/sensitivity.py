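"""Absolute sensitivity of twitch/transient biomarkers to model parameters.

The sensitivity of biomarker B to parameter p is the normalised central
difference

    S = [ (B(p*(1+d)) - B(p*(1-d))) / B(p) ] / (2 d)

i.e. fractional biomarker change per fractional parameter change, evaluated
at perturbation fraction ``d`` (default ±30%, ±50% for the troponin
dissociation rate).  Reported as |S|; unit-free, so sensitivities are
comparable across biomarkers.  Population results are summarised by the
median over models (robust to skewed biomarker distributions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import pandas as pd

from .biomarkers import BiomarkerSet, extract_biomarkers
from .params import CellParams, default_params
from .population import POP_MAX_BEATS, POP_SS_TOL, PopulationTable, simulate_population
from .simulate import run_to_steady_state

__all__ = ["SensitivityResult", "absolute_sensitivity", "sensitivity_matrix",
           "DEFAULT_DELTAS"]

#: default perturbation fractions per parameter (±30%; ±50% for k_off)
DEFAULT_DELTAS: dict[str, float] = {"Ca50": 0.3, "k_ub": 0.3, "k_off_trpn": 0.5}


def _default_simulate(params: CellParams) -> BiomarkerSet:
    res = run_to_steady_state(params, tol=POP_SS_TOL, max_beats=POP_MAX_BEATS)
    return extract_biomarkers(res.trace)


def absolute_sensitivity(
    params: CellParams,
    param_name: str,
    delta: float,
    biomarker_name: str,
    simulate_fn: Callable[[CellParams], BiomarkerSet] | None = None,
) -> float:
    """|S| for one parameter/biomarker pair on a single model.

    ``simulate_fn`` maps a parameter set to a BiomarkerSet (the paced
    steady-state twitch by default; injectable for testing).  Returns NaN if
    the biomarker is undefined at either perturbed point.
    """
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must lie in (0, 1)")
    fn = simulate_fn or _default_simulate
    vals = {}
    for scale in (1.0 - delta, 1.0, 1.0 + delta):
        bm = fn(params.scaled({param_name: scale}))
        vals[scale] = getattr(bm, biomarker_name)
    b0 = vals[1.0]
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals.values()):
        return math.nan
    if b0 == 0:
        return math.nan
    S = (vals[1.0 + delta] - vals[1.0 - delta]) / b0 / (2.0 * delta)
    return abs(S)


@dataclass
class SensitivityResult:
    """Median |S| matrix plus the per-model values behind it."""

    median_abs: pd.DataFrame          # index: parameter, columns: biomarker
    per_model: dict[tuple[str, str], pd.Series]
    deltas: Mapping[str, float]
    n_defined: pd.DataFrame

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for param in self.median_abs.index:
            for biom in self.median_abs.columns:
                rows.append({
                    "parameter": param, "biomarker": biom,
                    "delta": self.deltas[param],
                    "median_abs_S": self.median_abs.loc[param, biom],
                    "n_defined": int(self.n_defined.loc[param, biom]),
                })
        return pd.DataFrame(rows)


def sensitivity_matrix(
    population: PopulationTable | None,
    param_names: Sequence[str],
    biomarker_names: Sequence[str],
    deltas: Mapping[str, float] | None = None,
    base: CellParams | None = None,
    ss_tol: float = POP_SS_TOL,
    max_beats: int = POP_MAX_BEATS,
) -> SensitivityResult:
    """Population (or baseline-model) sensitivity matrix.

    With a calibrated population, each accepted model is perturbed and the
    per-model sensitivities are summarised by their median; with
    ``population=None`` the matrix is computed on the baseline model alone.
    Each perturbation direction is simulated as one warm-started batch.
    """
    base = default_params() if base is None else base
    deltas = {**DEFAULT_DELTAS, **(deltas or {})}
    for p in param_names:
        if p not in deltas:
            deltas[p] = 0.3

    if population is None:
        from .population import lhs_sample  # single-model pseudo-population
        population = lhs_sample(1, param_names=("Ca50",), seed=0)
        population.scales.iloc[0, 0] = 1.0
        population.accepted = pd.Series([True], index=population.scales.index)

    ids = population.accepted_ids()

    def batch(spec_factors) -> pd.DataFrame:
        from .scenarios import ScalingSpec
        spec = ScalingSpec("perturb", factors=spec_factors) if spec_factors else None
        warm = population.states.get("control")
        y0 = warm[[population.scales.index.get_loc(i) for i in ids]] if warm is not None else None
        bm, _, _ = simulate_population(
            population, base, spec=spec, ids=ids, y0=y0,
            ss_tol=ss_tol, max_beats=max_beats)
        return bm

    bm_mid = population.biomarkers.get("control")
    if bm_mid is None or not set(ids).issubset(bm_mid.index):
        bm_mid = batch(None)
    else:
        bm_mid = bm_mid.loc[ids]

    median = pd.DataFrame(index=list(param_names), columns=list(biomarker_names),
                          dtype=float)
    n_def = pd.DataFrame(0, index=list(param_names), columns=list(biomarker_names))
    per_model: dict[tuple[str, str], pd.Series] = {}
    for pname in param_names:
        d = deltas[pname]
        bm_lo = batch({pname: 1.0 - d})
        bm_hi = batch({pname: 1.0 + d})
        for biom in biomarker_names:
            S = (bm_hi[biom] - bm_lo[biom]) / bm_mid[biom] / (2.0 * d)
            absS = S.abs()
            per_model[(pname, biom)] = absS
            median.loc[pname, biom] = absS.median()
            n_def.loc[pname, biom] = int(absS.notna().sum())
    return SensitivityResult(median_abs=median, per_model=per_model,
                             deltas=deltas, n_defined=n_def)
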