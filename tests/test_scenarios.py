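import numpy as np
import pytest

from hcmcell.scenarios import (
    DEFAULT_MAVACAMTEN,
    DoseResponseParams,
    ScalingSpec,
    calibrate_dose_response,
    intervention_spec,
    mavacamten_R,
    mavacamten_spec,
    ng_per_ml_to_uM,
    variant_spec,
)


class TestVariantLibrary:
    def test_control_is_identity(self, base_params):
        assert variant_spec("control").apply(base_params) == base_params

    def test_myh7_sets_availability_and_feedback(self, base_params):
        p = variant_spec("MYH7_R403Q").apply(base_params)
        assert p.R == pytest.approx(1.3)
        assert p.fb_mode == "static"

    def test_tnnt2_rescales_sensitivity_and_tropomyosin(self, base_params):
        p = variant_spec("TNNT2_R92Q").apply(base_params)
        assert p.Ca50 == pytest.approx(0.7 * base_params.Ca50)
        assert p.k_ub == pytest.approx(0.8 * base_params.k_ub)

    def test_tnni3_rescales_sensitivity_and_dissociation(self, base_params):
        p = variant_spec("TNNI3_R21C").apply(base_params)
        assert p.Ca50 == pytest.approx(0.7 * base_params.Ca50)
        assert p.k_off_trpn == pytest.approx(0.5 * base_params.k_off_trpn)

    def test_unknown_variant_lists_valid_names(self):
        with pytest.raises(KeyError, match="TNNT2_R92Q"):
            variant_spec("MYH6_R403Q")


class TestScalingSpecValidation:
    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            ScalingSpec("bad", factors={"not_a_param": 1.1})

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            ScalingSpec("bad", factors={"Ca50": 0.0})


class TestMavacamtenDoseResponse:
    def test_zero_dose_is_neutral(self):
        dr = DoseResponseParams(E_max=0.8, IC50=0.5, hill_h=1.0)
        assert mavacamten_R(0.0, dr, R_base=1.3) == pytest.approx(1.3)

    def test_half_effect_at_ic50(self):
        dr = DoseResponseParams(E_max=0.8, IC50=0.5, hill_h=1.0)
        assert mavacamten_R(0.5, dr, R_base=1.0) == pytest.approx(1 - 0.4)

    def test_saturates_at_emax(self):
        dr = DoseResponseParams(E_max=0.8, IC50=0.5, hill_h=1.0)
        assert mavacamten_R(1e9, dr, R_base=1.0) == pytest.approx(0.2, abs=1e-6)

    def test_strictly_decreasing_in_dose(self):
        doses = np.linspace(0, 5, 30)
        rs = [mavacamten_R(c, DEFAULT_MAVACAMTEN, 1.3) for c in doses]
        assert all(b < a for a, b in zip(rs, rs[1:]))

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            mavacamten_R(-0.1, DEFAULT_MAVACAMTEN)

    def test_spec_composes_multiplicatively_on_variant_R(self, base_params):
        chain = variant_spec("MYH7_R403Q").compose(mavacamten_spec(0.5))
        p = chain.apply(base_params)
        expected = 1.3 * mavacamten_R(0.5, DEFAULT_MAVACAMTEN, 1.0)
        assert p.R == pytest.approx(expected)


class TestUnitConversion:
    def test_unit_algebra(self):
        assert ng_per_ml_to_uM(1000.0, molar_mass=1000.0, free_fraction=1.0) == pytest.approx(1.0)
        assert ng_per_ml_to_uM(0.0, molar_mass=500.0) == 0.0

    def test_linearity(self):
        one = ng_per_ml_to_uM(350.0, molar_mass=425.5, free_fraction=0.1)
        two = ng_per_ml_to_uM(700.0, molar_mass=425.5, free_fraction=0.1)
        assert two == pytest.approx(2 * one)

    def test_missing_molar_mass_is_config_error(self):
        with pytest.raises(ValueError, match="molar mass"):
            ng_per_ml_to_uM(500.0, molar_mass=None)


class TestInterventionLibrary:
    @pytest.mark.parametrize("kind, level, field, expected_factor", [
        ("ical_block", 0.4, "lcc_scale", 0.6),
        ("serca_up", 0.5, "serca_scale", 1.5),
        ("desensitiser", 0.5, "Ca50", 1.5),
    ])
    def test_multiplicative_kinds(self, base_params, kind, level, field, expected_factor):
        p = intervention_spec(kind, level).apply(base_params)
        assert getattr(p, field) == pytest.approx(
            expected_factor * getattr(base_params, field))

    def test_late_sodium_block_sets_fraction(self, base_params):
        p = intervention_spec("inal_block", 0.6).apply(base_params)
        assert p.inal_block == 0.6

    def test_reciprocal_desensitiser_mapping(self, base_params):
        p = intervention_spec("desensitiser", 0.5, reciprocal_desens=True).apply(base_params)
        assert p.Ca50 == pytest.approx(2.0 * base_params.Ca50)

    def test_unknown_kind_and_bad_level(self):
        with pytest.raises(KeyError):
            intervention_spec("caffeine", 0.2)
        with pytest.raises(ValueError):
            intervention_spec("serca_up", 1.0)


class TestDoseResponseCalibration:
    def test_single_target_under_determined(self, base_params):
        with pytest.raises(ValueError):
            calibrate_dose_response([(0.5, 0.8)], base_params)

    def test_round_trip_recovers_known_curve(self, base_params):
        # forward-simulate amplitude ratios under a known curve, then refit
        from hcmcell.biomarkers import extract_biomarkers
        from hcmcell.simulate import run_to_steady_state

        true = DoseResponseParams(E_max=0.7, IC50=0.8, hill_h=1.5)
        res0 = run_to_steady_state(base_params, tol=1e-5)
        amp0 = extract_biomarkers(res0.trace).tension_amp
        targets = []
        for conc in (0.4, 1.5):
            p = base_params.replace(R=mavacamten_R(conc, true, base_params.R))
            res = run_to_steady_state(p, tol=1e-5, y0=res0.state)
            targets.append((conc, extract_biomarkers(res.trace).tension_amp / amp0))
        fit = calibrate_dose_response(targets, base_params, hill_h=1.5,
                                      x0=(0.5, 0.5))
        assert fit.params.E_max == pytest.approx(true.E_max, rel=0.05)
        assert fit.params.IC50 == pytest.approx(true.IC50, rel=0.05)
        assert fit.max_abs_residual < 0.01
        assert "E_max" in fit.summary()
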