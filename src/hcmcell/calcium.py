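"""Reduced intracellular calcium-handling subsystem.

A three-state description of the cytosolic free calcium ``Cai`` (µM), the
sarcoplasmic-reticulum store ``Ca_sr`` (µM, in SR-volume units) and a
stimulus-triggered release gate ``g``:

* release     ``J_rel  = k_rel * g * Ca_sr`` with ``g`` incremented by
  ``g_amp`` at each pacing stimulus and decaying with ``tau_rel``;
* reuptake    ``J_serca`` -- Hill-saturating SERCA pump;
* extrusion   ``J_ncx   = k_ncx * (Cai - Ca_dia)`` -- lumped sarcolemmal
  efflux (sodium-calcium exchange and plasma-membrane pumps);
* trigger     ``J_in`` -- a square pulse of calcium entry at each stimulus
  standing in for the L-type current;
* fast buffering by calmodulin-class sites, treated as instantaneous via the
  rapid-buffer factor ``beta(Cai)``;
* slow, bidirectional troponin buffering supplied by the myofilament model
  (``J_trpn``), so troponin-kinetics remodelling reshapes the transient.

The intervention knobs (``lcc_scale``, ``serca_scale``, ``ncx_scale``,
``inal_block``) multiply the corresponding fluxes and implement L-type
block, SERCA upregulation and a phenomenological late-sodium-current block
(reduced sodium load -> stronger forward exchange, gain ``alpha_nal``).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CalciumParams",
    "CalciumState",
    "fast_buffer_factor",
    "calcium_fluxes",
    "calcium_derivatives",
]


@dataclass(frozen=True)
class CalciumParams:
    """Constants of the calcium subsystem (µM, ms).  Defaults are calibration
    values giving a control twitch with diastolic Cai near 0.1 µM and a
    transient amplitude in the 0.3-0.7 µM range at 1 Hz pacing."""

    g_amp: float = 1.0        # release-gate increment per stimulus
    tau_rel: float = 65.0     # ms, release gate decay
    k_rel: float = 0.002      # 1/ms, release rate constant
    V_serca: float = 1.22     # µM/ms, maximal SERCA uptake
    K_serca: float = 0.77     # µM, SERCA half-saturation
    h_serca: float = 2.8      # SERCA Hill coefficient
    k_ncx: float = 0.013       # 1/ms, extrusion rate constant
    Ca_dia: float = 0.053       # µM, extrusion reversal level
    A_in: float = 0.088         # µM/ms, trigger influx amplitude
    d_in: float = 30.0         # ms, trigger influx duration
    vr: float = 25.0          # cytosol-to-SR volume ratio
    B_cmdn: float = 50.0      # µM, fast-buffer capacity
    K_cmdn: float = 2.38      # µM, fast-buffer affinity
    TRPN_tot: float = 50.0    # µM, troponin buffer capacity
    lcc_scale: float = 1.0    # L-type trigger scaling (block = < 1)
    serca_scale: float = 1.0  # SERCA upregulation scaling
    ncx_scale: float = 1.0    # extrusion scaling
    inal_block: float = 0.0   # late-sodium block fraction in [0, 1]
    alpha_nal: float = 0.3    # coupling gain, late-sodium block -> extrusion

    def __post_init__(self) -> None:
        nonneg = (
            "g_amp", "tau_rel", "k_rel", "V_serca", "K_serca", "h_serca",
            "k_ncx", "Ca_dia", "A_in", "d_in", "vr", "B_cmdn", "K_cmdn",
            "TRPN_tot", "alpha_nal",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("lcc_scale", "serca_scale", "ncx_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.inal_block <= 1.0:
            raise ValueError("inal_block must lie in [0, 1]")


@dataclass
class CalciumState:
    Cai: float = 0.1     # µM free cytosolic calcium
    Ca_sr: float = 700.0  # µM SR calcium
    g: float = 0.0       # release gate

    def validate(self, tol: float = 1e-9) -> None:
        if self.Cai < -tol or self.Ca_sr < -tol or self.g < -tol:
            raise ValueError(f"negative calcium state: {self}")


def fast_buffer_factor(Cai: float, params: CalciumParams) -> float:
    """Rapid-buffering factor beta(Cai) = 1/(1 + B*K/(K + Cai)^2), in (0, 1]."""
    if Cai < 0:
        raise ValueError("Cai must be non-negative")
    K = params.K_cmdn
    return 1.0 / (1.0 + params.B_cmdn * K / (K + Cai) ** 2)


def calcium_fluxes(
    state: CalciumState, t_since_stim: float, params: CalciumParams
) -> tuple[float, float, float, float]:
    """Individual fluxes (J_rel, J_serca, J_ncx, J_in) in µM/ms."""
    J_rel = params.k_rel * state.g * state.Ca_sr
    cah = state.Cai ** params.h_serca
    J_serca = params.serca_scale * params.V_serca * cah / (cah + params.K_serca ** params.h_serca)
    J_ncx = (
        params.ncx_scale
        * (1.0 + params.alpha_nal * params.inal_block)
        * params.k_ncx
        * (state.Cai - params.Ca_dia)
    )
    J_in = params.lcc_scale * params.A_in if 0.0 <= t_since_stim < params.d_in else 0.0
    return J_rel, J_serca, J_ncx, J_in


def calcium_derivatives(
    state: CalciumState, J_trpn: float, t_since_stim: float, params: CalciumParams
) -> tuple[float, float, float]:
    """Time derivatives of (Cai, Ca_sr, g).

    ``J_trpn`` is the troponin-buffering flux from the myofilament model,
    positive when calcium leaves the free pool.  The release-gate increment
    at the stimulus instant is an event, not part of the vector field.
    """
    if t_since_stim < 0:
        raise ValueError("t_since_stim must be non-negative")
    state.validate()
    J_rel, J_serca, J_ncx, J_in = calcium_fluxes(state, t_since_stim, params)
    beta = fast_buffer_factor(state.Cai, params)
    dCai = beta * (J_in + J_rel - J_serca - J_ncx - J_trpn)
    dCa_sr = params.vr * (J_serca - J_rel)
    dg = -state.g / params.tau_rel if params.tau_rel > 0 else 0.0
    return dCai, dCa_sr, dg
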