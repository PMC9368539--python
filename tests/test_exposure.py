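import numpy as np
import pytest
from scipy import stats as sps

from crayrisk import (
    DistributionSpec,
    ExposureScenario,
    Tissue,
    edi_point,
    edible_intake,
    hazard_quotient,
    lhs_sample,
    lognormal_from_moments,
    percentile,
    run_simulation,
)
from crayrisk._rng import substream


class TestEdiPoint:
    def test_zero_concentration(self):
        assert edi_point(0.0, 10.54, 70.0) == 0.0

    def test_unit_cancellation_identity(self):
        assert edi_point(700.0, 1000.0, 1.0) == pytest.approx(700.0)

    def test_hepatopancreas_hand_arithmetic(self):
        assert edi_point(10.21, 1.26, 70.0) == pytest.approx(10.21 * 1.26 / 70000.0)
        assert edi_point(10.21, 1.26, 70.0) == pytest.approx(1.8378e-4, rel=1e-3)

    def test_nonpositive_body_weight_rejected(self):
        with pytest.raises(ValueError):
            edi_point(1.0, 1.0, 0.0)


class TestEdibleIntake:
    def test_muscle_intake_matches_reported_rate(self):
        assert edible_intake(10.54, 0.2000) == pytest.approx(2.108)
        assert round(edible_intake(10.54, 0.2000), 2) == 2.11

    def test_hepatopancreas_intake_matches_reported_rate(self):
        assert edible_intake(10.54, 0.1196) == pytest.approx(1.260584)
        assert round(edible_intake(10.54, 0.1196), 2) == 1.26

    def test_simple_ratio(self):
        assert edible_intake(2.0, 0.5) == pytest.approx(1.0)

    def test_ratio_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            edible_intake(10.54, 1.0)


class TestPercentile:
    def test_median_of_five(self):
        assert percentile(np.array([1, 2, 3, 4, 5]), 50) == pytest.approx(3.0)

    def test_p100_is_max(self):
        assert percentile(np.array([1, 2, 3, 4]), 100) == pytest.approx(4.0)

    def test_linear_interpolation(self):
        assert percentile(np.array([10.0, 20.0]), 95) == pytest.approx(19.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile(np.array([]), 50)


class TestHazardQuotient:
    def test_reported_adult_and_child_values(self):
        assert round(hazard_quotient(0.0014, 0.7).value, 3) == 0.002
        assert round(hazard_quotient(0.0049, 0.7).value, 3) == 0.007

    def test_zero_exposure_no_risk(self):
        hq = hazard_quotient(0.0, 0.7)
        assert hq.value == 0.0 and not hq.potential_risk

    def test_flag_above_one(self):
        assert hazard_quotient(1.4, 0.7).potential_risk

    def test_nonpositive_rfd_rejected(self):
        with pytest.raises(ValueError):
            hazard_quotient(0.1, 0.0)


class TestLatinHypercubeSampling:
    @pytest.mark.parametrize("n", [1, 2, 3, 7, 100, 1000])
    def test_exactly_one_draw_per_stratum(self, n):
        spec = lognormal_from_moments(20.98, 10.49)
        draws = lhs_sample(spec, n, seed=17)
        mu, sigma = spec.params
        u = sps.lognorm.cdf(draws, s=sigma, scale=np.exp(mu))
        strata = np.floor(u * n).astype(int)
        assert sorted(strata) == list(range(n))

    def test_point_mass_yields_constant(self):
        draws = lhs_sample(DistributionSpec("point_mass", (4.2,)), 25, seed=1)
        assert np.all(draws == 4.2)

    def test_reproducible_under_seed(self):
        spec = lognormal_from_moments(10.21, 3.30)
        np.testing.assert_array_equal(lhs_sample(spec, 100, 5), lhs_sample(spec, 100, 5))
        assert not np.array_equal(lhs_sample(spec, 100, 5), lhs_sample(spec, 100, 6))

    def test_sample_mean_tracks_analytic_mean(self):
        spec = lognormal_from_moments(20.98, 10.49)
        n = 1000
        se = spec.sd() / np.sqrt(n)
        hits = sum(
            abs(np.mean(lhs_sample(spec, n, substream(s, "lhs-mean"))) - spec.mean()) < 3 * se
            for s in range(100)
        )
        assert hits >= 99


class TestRunSimulation:
    def test_point_mass_collapse_equals_hand_arithmetic(self):
        scenario = ExposureScenario(
            cs_distributions={
                Tissue.abdominal_muscle: DistributionSpec("point_mass", (20.98,)),
                Tissue.hepatopancreas: DistributionSpec("point_mass", (10.21,)),
            },
            seed=0,
        )
        results = run_simulation(scenario)
        expected = (20.98 * 10.54 * 0.2000 + 10.21 * 10.54 * 0.1196) / (1000.0 * 70.0)
        adults = results["adults"]
        assert adults.edi_mean == pytest.approx(expected, rel=1e-12)
        assert adults.edi_sd == 0.0
        assert adults.edi_p95 == pytest.approx(expected, rel=1e-12)
        assert adults.hq == pytest.approx(expected / 0.7, rel=1e-12)
        assert not adults.potential_risk

    def test_children_to_adult_ratio_is_bw_ratio(self, default_scenario):
        results = run_simulation(default_scenario)
        np.testing.assert_allclose(
            results["children"].edi_samples,
            3.5 * results["adults"].edi_samples,
            rtol=1e-12,
        )
        assert results["children"].edi_mean / results["adults"].edi_mean == pytest.approx(
            3.5, rel=1e-12
        )

    def test_missing_tissue_spec_rejected(self):
        scenario = ExposureScenario(
            cs_distributions={Tissue.abdominal_muscle: lognormal_from_moments(20.98, 10.49)}
        )
        with pytest.raises(ValueError, match="hepatopancreas"):
            run_simulation(scenario)

    def test_single_tissue_mode_uses_total_intake(self):
        scenario = ExposureScenario(
            cs_distributions={Tissue.hepatopancreas: DistributionSpec("point_mass", (10.21,))},
            aggregation="single_tissue",
        )
        results = run_simulation(scenario)
        assert results["adults"].edi_mean == pytest.approx(10.21 * 10.54 / 70000.0, rel=1e-12)

    def test_deterministic_replay(self, default_scenario):
        first = run_simulation(default_scenario)
        second = run_simulation(default_scenario)
        for population in first:
            np.testing.assert_array_equal(
                first[population].edi_samples, second[population].edi_samples
            )

    def test_invariants_of_risk_result(self, default_scenario):
        for result in run_simulation(default_scenario).values():
            assert np.all(result.edi_samples >= 0)
            assert result.edi_p95 >= result.edi_median
            assert 0.0 <= result.tdi_compliance <= 100.0
            assert result.hq >= 0.0

    def test_stochastic_ratios_add_spread(self, default_scenario):
        stochastic = default_scenario.model_copy(update={"stochastic_ratios": True})
        fixed = run_simulation(default_scenario)["adults"]
        varied = run_simulation(stochastic)["adults"]
        assert varied.edi_sd > fixed.edi_sd * 0.9  # extra inputs never shrink spread much
        assert varied.edi_mean == pytest.approx(fixed.edi_mean, rel=0.05)

    def test_minimum_iterations_enforced(self):
        with pytest.raises(Exception):
            ExposureScenario(n_iterations=1)
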