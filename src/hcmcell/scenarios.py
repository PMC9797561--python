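"""Genotype library, myosin-inhibitor dose-response, and intervention library.

Genetic variants and pharmacological interventions are expressed as
:class:`ScalingSpec` objects: named multiplicative remodellings of the cell
parameters, optionally overriding the feedback mode or setting a parameter
outright.  The three HCM genotypes shipped here carry the remodellings
established from biophysical evidence:

* ``MYH7_R403Q``  -- myosin SRX destabilisation: DRX:SRX ratio R = 1.3 with
  the myosin -> thin-filament feedback enabled;
* ``TNNT2_R92Q``  -- altered tropomyosin positioning and calcium
  sensitisation: Ca50 x 0.7 and K_B x 0.8 (via its reverse rate ``k_ub``);
* ``TNNI3_R21C``  -- altered calcium binding to troponin: Ca50 x 0.7 and
  dissociation ``k_off`` x 0.5.

Mavacamten is modelled as an SRX stabiliser: a saturating dose-response
maps free concentration (µM) to a multiplicative reduction of R, composing
multiplicatively on top of any variant-set R.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .biomarkers import extract_biomarkers
from .params import CellParams
from .simulate import run_to_steady_state

__all__ = [
    "ScalingSpec", "DoseResponseParams", "DoseResponseFitResult",
    "variant_spec", "VARIANT_NAMES", "mavacamten_R", "mavacamten_spec",
    "calibrate_dose_response", "ng_per_ml_to_uM", "intervention_spec",
    "DEFAULT_MAVACAMTEN",
]

_PARAM_FIELDS = {f.name for f in dataclasses.fields(CellParams)}


@dataclass(frozen=True)
class ScalingSpec:
    """A named remodelling of cell parameters.

    ``factors`` multiply parameters; ``overrides`` set them outright
    (used for the release-gate-independent knobs such as ``inal_block``
    and for the feedback mode).
    """

    name: str
    factors: Mapping[str, float] = field(default_factory=dict)
    overrides: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, val in self.factors.items():
            if key not in _PARAM_FIELDS:
                raise KeyError(f"unknown parameter {key!r} in scaling spec {self.name!r}")
            if val <= 0:
                raise ValueError(f"factor for {key!r} must be > 0")
        for key in self.overrides:
            if key not in _PARAM_FIELDS:
                raise KeyError(f"unknown parameter {key!r} in scaling spec {self.name!r}")

    def apply(self, params: CellParams) -> CellParams:
        # overrides (e.g. a variant-set R) first, then multiplicative factors
        # on top, so composed drug factors act on the overridden value
        p = params.replace(**dict(self.overrides)) if self.overrides else params
        return p.scaled(self.factors)

    def compose(self, other: "ScalingSpec") -> "ScalingSpec":
        """This spec followed by ``other`` (factors multiply elementwise)."""
        factors = dict(self.factors)
        for k, v in other.factors.items():
            factors[k] = factors.get(k, 1.0) * v
        overrides = {**self.overrides, **other.overrides}
        return ScalingSpec(f"{self.name}+{other.name}", factors, overrides)


_VARIANTS: dict[str, ScalingSpec] = {
    "control": ScalingSpec("control"),
    "MYH7_R403Q": ScalingSpec("MYH7_R403Q", overrides={"R": 1.3, "fb_mode": "static"}),
    "TNNT2_R92Q": ScalingSpec("TNNT2_R92Q", factors={"Ca50": 0.7, "k_ub": 0.8}),
    "TNNI3_R21C": ScalingSpec("TNNI3_R21C", factors={"Ca50": 0.7, "k_off_trpn": 0.5}),
}

VARIANT_NAMES = tuple(_VARIANTS)


def variant_spec(name: str) -> ScalingSpec:
    """Look up a genotype remodelling by name."""
    try:
        return _VARIANTS[name]
    except KeyError:
        raise KeyError(
            f"unknown variant {name!r}; valid names: {', '.join(_VARIANTS)}"
        ) from None


@dataclass(frozen=True)
class DoseResponseParams:
    """Saturating dose-response mapping drug concentration to R reduction.

    ``R(conc) = R_base * (1 - E_max * conc^h / (conc^h + IC50^h))``.

    ``molar_mass`` (g/mol) and ``free_fraction`` support conversion of
    clinical plasma concentrations (ng/ml) to free µM; both must be supplied
    from a compound database for any real compound.
    """

    E_max: float = 0.5
    IC50: float = 0.5        # µM
    hill_h: float = 1.5
    molar_mass: float | None = None   # g/mol
    free_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.E_max <= 1.0:
            raise ValueError("E_max must lie in [0, 1]")
        if self.IC50 <= 0 or self.hill_h <= 0:
            raise ValueError("IC50 and hill_h must be positive")
        if not 0.0 < self.free_fraction <= 1.0:
            raise ValueError("free_fraction must lie in (0, 1]")


def mavacamten_R(conc_uM: float, dr: DoseResponseParams, R_base: float = 1.0) -> float:
    """Myosin availability R after the drug, at free concentration ``conc_uM``."""
    if conc_uM < 0:
        raise ValueError("concentration must be non-negative")
    ch = conc_uM ** dr.hill_h
    effect = dr.E_max * ch / (ch + dr.IC50 ** dr.hill_h) if conc_uM > 0 else 0.0
    return R_base * (1.0 - effect)


def mavacamten_spec(conc_uM: float, dr: "DoseResponseParams | None" = None) -> ScalingSpec:
    """Drug treatment as a multiplicative scaling of R (composes on variants)."""
    dr = DEFAULT_MAVACAMTEN if dr is None else dr
    factor = mavacamten_R(conc_uM, dr, R_base=1.0)
    return ScalingSpec(f"mavacamten_{conc_uM:g}uM", factors={"R": factor})


def ng_per_ml_to_uM(conc_ngml: float, molar_mass: float | None,
                    free_fraction: float = 1.0) -> float:
    """Convert a plasma concentration in ng/ml to free µM.

    ng/ml equals µg/l, so dividing by the molar mass in g/mol (= µg/µmol)
    yields µmol/l; the free fraction then discounts protein binding.
    """
    if molar_mass is None:
        raise ValueError("molar mass missing: supply it from a compound database")
    if conc_ngml < 0 or molar_mass <= 0 or not 0 < free_fraction <= 1:
        raise ValueError("invalid concentration-conversion inputs")
    return conc_ngml / molar_mass * free_fraction


INTERVENTION_KINDS = ("ical_block", "inal_block", "serca_up", "desensitiser")


def intervention_spec(kind: str, level: float, *, reciprocal_desens: bool = False) -> ScalingSpec:
    """A therapeutic intervention at the given fractional ``level``.

    ``ical_block``    -- L-type calcium current block (trigger x (1-level)),
    ``inal_block``    -- late sodium current block (phenomenological),
    ``serca_up``      -- SERCA upregulation (uptake x (1+level)),
    ``desensitiser``  -- thin-filament calcium desensitisation
                         (Ca50 x (1+level), or x 1/(1-level) if reciprocal).
    """
    if not 0.0 <= level < 1.0:
        raise ValueError("level must lie in [0, 1)")
    name = f"{kind}_{level:g}"
    if kind == "ical_block":
        return ScalingSpec(name, factors={"lcc_scale": 1.0 - level})
    if kind == "inal_block":
        return ScalingSpec(name, overrides={"inal_block": level})
    if kind == "serca_up":
        return ScalingSpec(name, factors={"serca_scale": 1.0 + level})
    if kind == "desensitiser":
        factor = 1.0 / (1.0 - level) if reciprocal_desens else 1.0 + level
        return ScalingSpec(name, factors={"Ca50": factor})
    raise KeyError(
        f"unknown intervention {kind!r}; valid kinds: {', '.join(INTERVENTION_KINDS)}"
    )


# ---------------------------------------------------------------------------
# dose-response calibration
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseFitResult:
    """Least-squares calibration result for the dose -> R mapping."""

    params: DoseResponseParams
    residuals: np.ndarray
    targets: list[tuple[float, float]]
    n_evals: int

    @property
    def max_abs_residual(self) -> float:
        return float(np.max(np.abs(self.residuals)))

    def summary(self) -> str:
        lines = [
            "Dose-response calibration (amplitude-ratio targets)",
            f"  E_max = {self.params.E_max:.4f}",
            f"  IC50  = {self.params.IC50:.4f} µM",
            f"  h     = {self.params.hill_h:.4f} (fixed)",
            f"  max |residual| = {self.max_abs_residual:.4f}",
        ]
        for (conc, tgt), r in zip(self.targets, self.residuals):
            lines.append(f"    {conc:g} µM: target {tgt:.3f}, residual {r:+.4f}")
        return "\n".join(lines)


def calibrate_dose_response(
    target_points: Sequence[tuple[float, float]],
    params_base: CellParams,
    spec: ScalingSpec | None = None,
    hill_h: float = 1.5,
    x0: tuple[float, float] = (0.5, 0.5),
    ss_tol: float = 1e-5,
    max_beats: int = 300,
) -> DoseResponseFitResult:
    """Fit (E_max, IC50) so simulated steady-twitch amplitude ratios match.

    ``target_points`` are ``(conc_uM, amplitude ratio vs untreated)`` pairs
    for the scenario given by ``spec`` (default: the untreated ``params_base``
    itself).  The fit is a deterministic bounded least-squares from a fixed
    start point.
    """
    if len(target_points) < 2:
        raise ValueError("dose-response calibration needs at least 2 target points")
    p_untreated = spec.apply(params_base) if spec is not None else params_base
    base_res = run_to_steady_state(p_untreated, tol=ss_tol, max_beats=max_beats)
    amp0 = extract_biomarkers(base_res.trace).tension_amp
    if amp0 <= 0:
        raise RuntimeError("untreated scenario has zero tension amplitude")
    warm = base_res.state
    n_evals = 0

    def residual(x):
        nonlocal n_evals
        dr = DoseResponseParams(E_max=min(max(x[0], 0.0), 1.0),
                                IC50=max(x[1], 1e-4), hill_h=hill_h)
        out = []
        for conc, target in target_points:
            p = p_untreated.replace(R=mavacamten_R(conc, dr, p_untreated.R))
            res = run_to_steady_state(p, tol=ss_tol, max_beats=max_beats, y0=warm)
            amp = extract_biomarkers(res.trace).tension_amp
            out.append(amp / amp0 - target)
            n_evals += 1
        return np.array(out)

    fit = least_squares(residual, x0=np.array(x0), bounds=([0.0, 1e-3], [1.0, 50.0]),
                        diff_step=0.05, xtol=1e-6, ftol=1e-8)
    if not fit.success:
        raise RuntimeError(
            f"dose-response calibration did not converge: {fit.message}; "
            f"residuals {fit.fun}"
        )
    dr = DoseResponseParams(E_max=float(fit.x[0]), IC50=float(fit.x[1]), hill_h=hill_h)
    return DoseResponseFitResult(params=dr, residuals=fit.fun,
                                 targets=list(target_points), n_evals=n_evals)


#: Shipped dose-response for Mavacamten, calibrated with
#: :func:`calibrate_dose_response` against the default MYH7_R403Q model so the
#: 0.5 µM reference dose restores control tension amplitude (see docs).
DEFAULT_MAVACAMTEN = DoseResponseParams(E_max=1.0, IC50=1.0842, hill_h=1.5)
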