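import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hcmcell.myofilament import (
    MyofilamentParams,
    MyofilamentState,
    active_tension,
    availability_scale,
    ca50_effective,
    drx_fraction,
    myofilament_derivatives,
    troponin_flux,
)


class TestDrxFraction:
    @pytest.mark.parametrize(
        "R, rho0, expected",
        [(1.0, 1.0, 0.5), (1.3, 1.0, 1.3 / 2.3), (1e9, 1.0, pytest.approx(1.0, abs=1e-8))],
    )
    def test_known_values(self, R, rho0, expected):
        assert drx_fraction(R, rho0) == pytest.approx(expected)

    @pytest.mark.parametrize("R, rho0", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)])
    def test_domain_errors(self, R, rho0):
        with pytest.raises(ValueError):
            drx_fraction(R, rho0)

    @given(st.floats(0.01, 100), st.floats(0.01, 100), st.floats(1.0001, 10))
    def test_strictly_increasing_in_R(self, R, rho0, factor):
        assert drx_fraction(R * factor, rho0) > drx_fraction(R, rho0)
        assert 0 < drx_fraction(R, rho0) < 1


class TestAvailabilityScale:
    @pytest.mark.parametrize(
        "R, expected",
        [(1.0, 1.0), (1.3, pytest.approx((1.3 / 2.3) / 0.5)),
         (0.5, pytest.approx((1 / 3) / 0.5))],
    )
    def test_known_values(self, R, expected):
        assert availability_scale(R, 1.0) == expected

    @given(st.floats(0.02, 50))
    def test_unity_at_control(self, rho0):
        assert availability_scale(1.0, rho0) == pytest.approx(1.0)


class TestCa50Feedback:
    def test_off_is_identity(self):
        p = MyofilamentParams(Ca50=0.8, fb_mode="off", R=1.3, gamma_fb=0.5)
        assert ca50_effective(p) == 0.8

    def test_static_inactive_at_control_R(self):
        p = MyofilamentParams(Ca50=0.8, fb_mode="static", R=1.0, gamma_fb=0.7)
        assert ca50_effective(p) == pytest.approx(0.8)

    def test_static_sensitises_with_more_drx(self):
        p = MyofilamentParams(Ca50=0.8, fb_mode="static", R=1.3, gamma_fb=0.5)
        assert ca50_effective(p) == pytest.approx(0.8 * (1 - 0.15))

    @given(st.floats(0.1, 3.0), st.floats(0.0, 5.0))
    def test_static_factor_respects_bounds(self, R, gamma):
        p = MyofilamentParams(fb_mode="static", R=R, gamma_fb=gamma, fb_bounds=(0.5, 1.5))
        lo, hi = p.fb_bounds
        assert lo * p.Ca50 <= ca50_effective(p) <= hi * p.Ca50

    def test_dynamic_uses_crossbridge_occupancy(self):
        p = MyofilamentParams(Ca50=1.0, fb_mode="dynamic", gamma_fb=0.5, fb_ws_ref=0.1)
        quiet = MyofilamentState(CaTRPN=0.1, B=0.9, W=0.0, S=0.0)
        active = MyofilamentState(CaTRPN=0.3, B=0.5, W=0.1, S=0.1)
        assert ca50_effective(p, active) < ca50_effective(p, quiet)


class TestDerivatives:
    def test_catrpn_equilibrium_at_half_occupancy(self):
        # Cai held at effective Ca50 with k_on == k_off: c = 0.5 is a fixed point
        p = MyofilamentParams(k_on_trpn=0.1, k_off_trpn=0.1)
        s = MyofilamentState(CaTRPN=0.5, B=0.9, W=0.0, S=0.0)
        dc, _, _, _ = myofilament_derivatives(s, Cai=p.Ca50, params=p)
        assert dc == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("cai_rel", [0.3, 1.0, 2.5])
    def test_catrpn_steady_state_closed_form(self, cai_rel):
        # c_ss = x/(1+x), x = (Cai/Ca50)^n, for symmetric rates
        p = MyofilamentParams(k_on_trpn=0.05, k_off_trpn=0.05)
        x = cai_rel ** p.n_trpn
        c_ss = x / (1 + x)
        s = MyofilamentState(CaTRPN=c_ss, B=0.9, W=0.0, S=0.0)
        dc, _, _, _ = myofilament_derivatives(s, Cai=cai_rel * p.Ca50, params=p)
        assert dc == pytest.approx(0.0, abs=1e-12)

    def test_zero_calcium_drains_troponin_and_blocks(self):
        p = MyofilamentParams()
        s = MyofilamentState(CaTRPN=0.3, B=0.5, W=0.05, S=0.05)
        dc, dB, _, _ = myofilament_derivatives(s, Cai=0.0, params=p)
        assert dc == pytest.approx(-p.k_off_trpn * 0.3)
        assert dB > 0  # tropomyosin relaxes toward blocked

    def test_blocked_unblocked_equilibrium_closed_form(self):
        # with crossbridge rates ~0 and constant CaTRPN, B/U settles at
        # k_ub * min(c^(-n_tm/2), cap) / (k_bu * c^(n_tm/2))
        from scipy.integrate import odeint

        p = MyofilamentParams(k_uw=1e-12, k_ws=1e-12, k_su=1e-12, k_wu=1e-12)
        c = 0.2

        def rhs(y, t):
            s = MyofilamentState(CaTRPN=c, B=y[0], W=0.0, S=0.0)
            _, dB, _, _ = myofilament_derivatives(s, Cai=0.5, params=p)
            return [dB]

        B_end = odeint(rhs, [0.5], [0.0, 5000.0])[-1, 0]
        half = 0.5 * p.n_tm
        ratio = p.k_ub * min(c ** -half, p.trpn_cap) / (p.k_bu * c ** half)
        assert B_end / (1 - B_end) == pytest.approx(ratio, rel=1e-6)

    def test_negative_calcium_rejected(self):
        with pytest.raises(ValueError):
            myofilament_derivatives(MyofilamentState(), -0.1, MyofilamentParams())

    def test_invalid_state_rejected(self):
        s = MyofilamentState(CaTRPN=0.5, B=0.8, W=0.3, S=0.2)  # B+W+S > 1
        with pytest.raises(ValueError):
            myofilament_derivatives(s, 0.5, MyofilamentParams())


class TestActiveTension:
    def test_zero_strong_fraction_gives_zero(self):
        assert active_tension(MyofilamentState(S=0.0), MyofilamentParams()) == 0.0

    def test_proportional_to_strong_fraction_and_tref(self):
        p = MyofilamentParams(T_ref=120.0)
        s = MyofilamentState(CaTRPN=0.3, B=0.5, W=0.1, S=0.1)
        assert active_tension(s, p) == pytest.approx(12.0)
        p2 = MyofilamentParams(T_ref=240.0)
        assert active_tension(s, p2) == pytest.approx(2 * active_tension(s, p))


class TestTroponinFlux:
    def test_equilibrium_flux_is_zero(self):
        p = MyofilamentParams(k_on_trpn=0.05, k_off_trpn=0.05)
        x = 1.0  # Cai == Ca50
        s = MyofilamentState(CaTRPN=x / (1 + x), B=0.9, W=0.0, S=0.0)
        assert troponin_flux(s, p.Ca50, p, TRPN_tot=50.0) == pytest.approx(0.0, abs=1e-10)

    def test_sign_matches_occupancy_derivative(self):
        p = MyofilamentParams()
        s = MyofilamentState(CaTRPN=0.05, B=0.9, W=0.0, S=0.0)
        dc = myofilament_derivatives(s, 1.5, p)[0]
        assert math.copysign(1, troponin_flux(s, 1.5, p, 50.0)) == math.copysign(1, dc)

    def test_halved_dissociation_weakens_release_flux(self):
        # at a fixed state during decay (occupancy above equilibrium), the
        # release flux magnitude is smaller when k_off is halved
        p = MyofilamentParams()
        p_slow = MyofilamentParams(k_off_trpn=p.k_off_trpn * 0.5)
        s = MyofilamentState(CaTRPN=0.6, B=0.5, W=0.05, S=0.05)
        j_fast = troponin_flux(s, 0.2, p, 50.0)
        j_slow = troponin_flux(s, 0.2, p_slow, 50.0)
        assert j_fast < 0 and j_slow < 0
        assert abs(j_slow) < abs(j_fast)


class TestParamValidation:
    @pytest.mark.parametrize("kw", [
        {"Ca50": 0.0}, {"R": -1.0}, {"n_trpn": 0.5}, {"trpn_cap": 0.5},
        {"fb_mode": "sometimes"}, {"fb_bounds": (0.01, 1.0)},
    ])
    def test_invariants_enforced(self, kw):
        with pytest.raises(ValueError):
            MyofilamentParams(**kw)
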