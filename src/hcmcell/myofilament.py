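"""Active-contraction model of the human cardiac myofilament.

The contractile unit is described by four fractional state variables:

* ``CaTRPN`` -- fractional calcium occupancy of troponin C,
* ``B``      -- tropomyosin in the blocked (off) position,
* ``W``      -- weakly bound (pre-powerstroke) crossbridges,
* ``S``      -- strongly bound, force-generating crossbridges,

with the unblocked, crossbridge-free fraction ``U = 1 - B - W - S`` implicit.
Troponin calcium binding follows a Hill-type ODE driven by free cytosolic
calcium relative to ``Ca50`` (the concentration at half-maximal thin-filament
activation, in µM).  Tropomyosin switches between the blocked and unblocked
positions with a CaTRPN-dependent cooperative equilibrium (the ``K_B`` knob:
scaling the reverse rate ``k_ub`` rescales that equilibrium).  Crossbridges
cycle U -> W -> S -> U; under the fixed-extension (isometric) simplification
active tension is ``T_ref * S``.

Myosin head availability enters through ``R``, the DRX:SRX odds relative to
control.  Myosin heads in the super-relaxed (SRX) conformation cannot bind
actin; only the disordered-relaxed (DRX) fraction drives contraction.  ``R``
scales the crossbridge attachment rate via :func:`availability_scale`, and an
optional positive feedback of myosin-based activation on thin-filament
calcium sensitivity rescales ``Ca50`` (see :func:`ca50_effective`).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MyofilamentParams",
    "MyofilamentState",
    "drx_fraction",
    "availability_scale",
    "ca50_effective",
    "feedback_factor",
    "myofilament_derivatives",
    "active_tension",
    "troponin_flux",
]

#: numerical tolerance for occupancy invariants during integration
OCCUPANCY_TOL = 1e-9

FB_MODES = ("off", "static", "dynamic")


@dataclass(frozen=True)
class MyofilamentParams:
    """Constants of the myofilament subsystem.

    Rates are in 1/ms, concentrations in µM, tension in kPa.  Defaults are
    calibration values chosen so the control steady twitch at 1 Hz pacing has
    physiological tension amplitude and relaxation times; they are tunable
    knobs, not measured constants.
    """

    Ca50: float = 0.96          # µM, half-maximal thin-filament activation
    n_trpn: float = 2.0         # troponin Hill coefficient
    k_on_trpn: float = 0.032      # 1/ms, occupancy-driving rate
    k_off_trpn: float = 0.0224     # 1/ms, calcium dissociation from troponin
    n_tm: float = 2.2           # tropomyosin cooperativity exponent
    k_bu: float = 0.15          # 1/ms, blocked -> unblocked base rate
    k_ub: float = 0.015         # 1/ms, unblocked -> blocked (the K_B knob)
    trpn_cap: float = 100.0     # cap on the CaTRPN^(-n_tm/2) factor
    k_uw: float = 0.18          # 1/ms, unblocked -> weak attachment
    k_wu: float = 0.3          # 1/ms, weak detachment
    k_ws: float = 0.02          # 1/ms, weak -> strong (powerstroke)
    k_su: float = 0.02          # 1/ms, strong detachment
    T_ref: float = 120.0        # kPa, reference maximal tension
    rho0: float = 1.0           # control DRX:SRX odds
    R: float = 1.0              # DRX:SRX odds relative to control
    gamma_fb: float = 0.63       # myosin -> thin-filament feedback gain
    fb_mode: str = "off"        # {off, static, dynamic}
    fb_bounds: tuple[float, float] = (0.5, 1.5)
    fb_ws_ref: float = 0.10     # control peak W+S, dynamic-feedback reference
    r_scales_tref: bool = False  # alternative: R scales T_ref instead of k_uw

    def __post_init__(self) -> None:
        positive = (
            "Ca50", "k_on_trpn", "k_off_trpn", "k_bu", "k_ub",
            "k_uw", "k_wu", "k_ws", "k_su", "T_ref", "rho0", "R",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_trpn < 1:
            raise ValueError("n_trpn must be >= 1")
        if self.n_tm < 0:
            raise ValueError("n_tm must be >= 0")
        if self.trpn_cap < 1:
            raise ValueError("trpn_cap must be >= 1")
        if self.fb_mode not in FB_MODES:
            raise ValueError(f"fb_mode must be one of {FB_MODES}")
        lo, hi = self.fb_bounds
        if not (0.1 <= lo <= hi <= 10.0):
            raise ValueError("fb_bounds must satisfy 0.1 <= lo <= hi <= 10")


@dataclass
class MyofilamentState:
    """Fractional occupancies of the contractile unit."""

    CaTRPN: float = 0.02
    B: float = 0.9
    W: float = 0.0
    S: float = 0.0

    @property
    def U(self) -> float:
        return 1.0 - self.B - self.W - self.S

    def validate(self, tol: float = OCCUPANCY_TOL) -> None:
        vals = (self.CaTRPN, self.B, self.W, self.S, self.U)
        if any(v < -tol or v > 1.0 + tol for v in vals):
            raise ValueError(f"myofilament state outside [0,1]: {self}")


def drx_fraction(R: float, rho0: float = 1.0) -> float:
    """Fraction of myosin heads in the DRX (actin-available) conformation.

    With control odds ``rho0 = DRX/SRX`` and relative odds ``R``, the DRX
    fraction is ``R*rho0 / (1 + R*rho0)``: strictly increasing in ``R`` and
    saturating at 1.
    """
    if R <= 0 or rho0 <= 0:
        raise ValueError("R and rho0 must be strictly positive")
    odds = R * rho0
    return odds / (1.0 + odds)


def availability_scale(R: float, rho0: float = 1.0) -> float:
    """Multiplier on crossbridge attachment due to myosin availability.

    Normalised so the control model (``R = 1``) is unchanged.
    """
    return drx_fraction(R, rho0) / drx_fraction(1.0, rho0)


def feedback_factor(params: MyofilamentParams, ws_occupancy: float | None = None) -> float:
    """Scaling factor applied to Ca50 by the myosin -> thin-filament feedback.

    ``static`` mode derives the factor from the availability parameter R
    alone (``1 - gamma_fb*(R - 1)``); ``dynamic`` mode derives it from the
    instantaneous crossbridge occupancy ``W + S`` relative to the configured
    control peak.  A factor below 1 means sensitisation (more available
    myosin activates the thin filament).  Always clipped into ``fb_bounds``.
    """
    lo, hi = params.fb_bounds
    if params.fb_mode == "off":
        return 1.0
    if params.fb_mode == "static":
        raw = 1.0 - params.gamma_fb * (params.R - 1.0)
    elif params.fb_mode == "dynamic":
        if ws_occupancy is None:
            raise ValueError("dynamic feedback requires the W+S occupancy")
        raw = 1.0 - params.gamma_fb * (ws_occupancy / params.fb_ws_ref - 1.0)
    else:  # pragma: no cover - guarded by __post_init__
        raise ValueError(params.fb_mode)
    return min(max(raw, lo), hi)


def ca50_effective(params: MyofilamentParams, state: MyofilamentState | None = None) -> float:
    """Effective Ca50 (µM) after the myosin-based feedback, if enabled."""
    ws = None
    if params.fb_mode == "dynamic":
        if state is None:
            raise ValueError("dynamic feedback requires a state")
        ws = state.W + state.S
    return params.Ca50 * feedback_factor(params, ws)


def myofilament_derivatives(
    state: MyofilamentState, Cai: float, params: MyofilamentParams
) -> tuple[float, float, float, float]:
    """Time derivatives of (CaTRPN, B, W, S) at free calcium ``Cai`` (µM)."""
    if Cai < 0:
        raise ValueError("Cai must be non-negative")
    state.validate()
    c = min(max(state.CaTRPN, 1e-12), 1.0)
    U = state.U

    ca50_eff = ca50_effective(params, state)
    dCaTRPN = (
        params.k_on_trpn * (Cai / ca50_eff) ** params.n_trpn * (1.0 - c)
        - params.k_off_trpn * c
    )

    half = 0.5 * params.n_tm
    gain = min(c ** (-half), params.trpn_cap)
    dB = params.k_ub * gain * U - params.k_bu * c ** half * state.B

    avail = availability_scale(params.R, params.rho0)
    k_attach = params.k_uw if params.r_scales_tref else params.k_uw * avail
    dW = k_attach * U - (params.k_wu + params.k_ws) * state.W
    dS = params.k_ws * state.W - params.k_su * state.S
    return dCaTRPN, dB, dW, dS


def active_tension(state: MyofilamentState, params: MyofilamentParams) -> float:
    """Isometric active tension T_a = T_ref * S (kPa), at extension ratio 1."""
    scale = availability_scale(params.R, params.rho0) if params.r_scales_tref else 1.0
    return params.T_ref * scale * state.S


def troponin_flux(
    state: MyofilamentState, Cai: float, params: MyofilamentParams, TRPN_tot: float
) -> float:
    """Calcium flux into the troponin buffer, µM/ms (positive = leaving the free pool)."""
    dCaTRPN, _, _, _ = myofilament_derivatives(state, Cai, params)
    return TRPN_tot * dCaTRPN
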