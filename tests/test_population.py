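import numpy as np
import pandas as pd
import pytest

from hcmcell.population import (
    CalibrationRanges,
    DEFAULT_AXES,
    apply_calibration,
    calibrate_population,
    lhs_sample,
    run_population,
    simulate_population,
)
from hcmcell.scenarios import ScalingSpec, variant_spec
from hcmcell.synthetic import synth_calibration_ranges


class TestLhsSampling:
    def test_one_sample_per_stratum(self):
        table = lhs_sample(4, param_names=("Ca50",), seed=3)
        vals = np.sort(table.scales["Ca50"].to_numpy())
        edges = np.linspace(0.5, 2.0, 5)
        for v, lo, hi in zip(vals, edges[:-1], edges[1:]):
            assert lo <= v <= hi

    def test_reproducible_for_fixed_seed(self):
        a = lhs_sample(20, seed=11).scales
        b = lhs_sample(20, seed=11).scales
        pd.testing.assert_frame_equal(a, b)
        c = lhs_sample(20, seed=12).scales
        assert not a.equals(c)

    def test_large_sample_respects_bounds_and_strata(self):
        n = 2000
        table = lhs_sample(n, seed=0)
        for name in DEFAULT_AXES:
            col = table.scales[name].to_numpy()
            assert col.min() >= 0.5 and col.max() <= 2.0
            strata = np.floor((col - 0.5) / 1.5 * n).astype(int)
            assert len(np.unique(strata)) == n  # exactly one per stratum

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lhs_sample(0)
        with pytest.raises(ValueError):
            lhs_sample(5, param_names=("Ca50",), ranges={"Ca50": (2.0, 0.5)})


class TestCalibrationRanges:
    def test_type_invariants(self):
        with pytest.raises(ValueError):
            CalibrationRanges({"tension_amp": (5.0, 1.0)})
        with pytest.raises(KeyError):
            CalibrationRanges({"not_a_biomarker": (0.0, 1.0)})

    def test_yaml_round_trip(self, tmp_path):
        r = CalibrationRanges({"tension_amp": (1.0, 30.0), "ca_amp": (0.2, 1.5)})
        path = tmp_path / "ranges.yaml"
        r.to_yaml(path)
        back = CalibrationRanges.from_yaml(path)
        assert dict(back) == dict(r)


@pytest.fixture(scope="module")
def small_population(base_params):
    """12-model population simulated at control (shared in this module)."""
    table = lhs_sample(12, seed=5)
    bm, states, converged = simulate_population(table, base_params)
    table.biomarkers["control"] = bm
    table.states["control"] = states
    table.accepted = pd.Series(converged, index=bm.index)
    return table


class TestCalibration:
    def test_unbounded_ranges_accept_everyone(self, small_population):
        r = CalibrationRanges({"tension_amp": (-np.inf, np.inf),
                               "ca_amp": (-np.inf, np.inf)})
        t = apply_calibration(small_population, r)
        assert t.accepted.all()

    def test_disjoint_ranges_reject_everyone_with_tallies(self, small_population):
        r = CalibrationRanges({"tension_amp": (1e6, 2e6), "ca_amp": (1e6, 2e6)})
        with pytest.warns(RuntimeWarning):
            t = apply_calibration(small_population, r)
        assert t.n_accepted == 0
        assert t.rejection_tallies.sum() >= t.n_models

    def test_percentile_ranges_accept_a_strict_subset(self, small_population):
        ranges = synth_calibration_ranges(small_population, 20.0, 80.0)
        t = apply_calibration(small_population, ranges)
        # direct counting oracle: a model is accepted iff inside every range
        bm = t.biomarkers["control"]
        inside = pd.Series(True, index=bm.index)
        for name, (lo, hi) in ranges:
            inside &= (bm[name] >= lo) & (bm[name] <= hi)
        assert (t.accepted == inside).all()
        assert 0 < t.n_accepted < t.n_models

    def test_calibrate_population_end_to_end(self, base_params):
        table = lhs_sample(6, seed=9)
        r = CalibrationRanges({"tension_amp": (0.0, np.inf)})
        t = calibrate_population(table, r, base_params)
        assert "control" in t.biomarkers
        assert t.accepted.notna().all()


class TestScenarioRuns:
    def test_identity_scaling_reproduces_calibration_biomarkers(
            self, small_population, base_params):
        t = run_population(small_population, ScalingSpec("identity"), base_params,
                           scenario_name="identity")
        ids = t.accepted_ids()
        a = t.biomarkers["control"].loc[ids]
        b = t.biomarkers["identity"].loc[ids]
        for col in ("tension_amp", "ca_amp", "tension_rt90"):
            np.testing.assert_allclose(b[col], a[col], rtol=1e-3)

    def test_myosin_variant_raises_every_models_amplitude(
            self, small_population, base_params):
        t = run_population(small_population, variant_spec("MYH7_R403Q"), base_params)
        ids = t.accepted_ids()
        ctrl = t.biomarkers["control"].loc[ids, "tension_amp"]
        myh7 = t.biomarkers["MYH7_R403Q"].loc[ids, "tension_amp"]
        assert (myh7 > ctrl).all()

    def test_uncalibrated_population_rejected(self, base_params):
        table = lhs_sample(3, seed=2)
        with pytest.raises(ValueError):
            run_population(table, variant_spec("control"), base_params)


class TestScalingComposition:
    def test_factor_composition_equals_product(self, base_params):
        a = ScalingSpec("a", factors={"Ca50": 0.8, "V_serca": 1.2})
        b = ScalingSpec("b", factors={"Ca50": 1.5})
        combined = a.compose(b).apply(base_params)
        stepwise = b.apply(a.apply(base_params))
        assert combined.Ca50 == pytest.approx(stepwise.Ca50)
        assert combined.Ca50 == pytest.approx(base_params.Ca50 * 1.2)
        assert combined.V_serca == pytest.approx(base_params.V_serca * 1.2)

    def test_acceptance_deterministic(self, small_population):
        ranges = synth_calibration_ranges(small_population, 10.0, 90.0)
        a = apply_calibration(small_population, ranges).accepted.copy()
        b = apply_calibration(small_population, ranges).accepted.copy()
        assert (a == b).all()


class TestTableIO:
    def test_csv_round_trip_preserves_scales_and_flags(self, small_population, tmp_path):
        path = tmp_path / "pop.csv"
        small_population.to_csv(path)
        from hcmcell.population import PopulationTable

        back = PopulationTable.from_csv(path)
        pd.testing.assert_frame_equal(
            back.scales, small_population.scales, check_exact=False, rtol=1e-9)
        assert "control" in back.biomarkers
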