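"""Estimator: residual contract, R^2, active-set discipline, recovery."""

import numpy as np
import pandas as pd
import pytest

from maillard_kinetics import (
    RateConstants,
    build_model_system,
    check_start_robustness,
    fit_multiresponse,
    generate_dataset,
    natural_to_printed,
    r2_per_response,
    refit_from_simulation,
    residual_vector,
    table1_scenario,
)
from maillard_kinetics.synthetic_data import Dataset, NoiseModel


def _manual_dataset(spec, rows):
    obs = pd.DataFrame(rows, columns=["time_min", "replicate", "species", "value"])
    return Dataset(spec=spec, observations=obs)


class TestResidualVector:
    def test_perfect_prediction_gives_zero_residuals(self, com_scenario):
        ds = generate_dataset(com_scenario.spec, com_scenario.k, NoiseModel(cv=0.0), 1)
        r = residual_vector(com_scenario.k, ds, com_scenario.spec)
        assert np.max(np.abs(r)) < 1e-6

    def test_definition_single_observation(self):
        # one GLU observation of 2 against a constant prediction of 1,
        # max weighting -> residual (2 - 1)/2 = 0.5
        spec = build_model_system("Lys/Glu", 170, initial_mmolL={"GLU": 1.0, "LYS": 0.0})
        ds = _manual_dataset(spec, [(3.0, 1, "GLU", 2.0)])
        r = residual_vector(RateConstants.zeros(), ds, spec, weighting="max")
        np.testing.assert_allclose(r, [0.5])

    def test_one_residual_per_observation_minus_exclusions(self, com_scenario):
        # Com/Glu reaches all 14 species, so nothing is excluded
        ds = generate_dataset(com_scenario.spec, com_scenario.k, NoiseModel(cv=0.05, seed=1), 3)
        r = residual_vector(com_scenario.k, ds, com_scenario.spec)
        assert len(r) == 8 * 3 * 14

    def test_all_zero_species_excluded(self):
        sc = table1_scenario("Lys-Glu-170")
        ds = generate_dataset(sc.spec, sc.k, NoiseModel(cv=0.05, seed=1), 3)
        r = residual_vector(sc.k, ds, sc.spec)
        # ASN, TRP, AA, HAR, NOR are identically zero in the Lys system
        assert len(r) == 8 * 3 * (14 - 5)

    def test_out_of_protocol_times_rejected(self, com_scenario):
        ds = _manual_dataset(com_scenario.spec, [(25.0, 1, "GLU", 1.0)])
        with pytest.raises(ValueError, match=r"\[0, 21\]"):
            residual_vector(com_scenario.k, ds, com_scenario.spec)

    def test_unknown_weighting_scheme_rejected(self, com_scenario):
        ds = generate_dataset(com_scenario.spec, com_scenario.k, NoiseModel(cv=0.0), 1)
        with pytest.raises(ValueError, match="scheme"):
            residual_vector(com_scenario.k, ds, com_scenario.spec, weighting="huber")


class TestR2:
    def test_perfect_fit_is_one(self):
        assert r2_per_response([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_prediction_is_zero(self):
        assert r2_per_response([1.0, 2.0, 3.0], [2.0, 2.0, 2.0]) == pytest.approx(0.0)

    def test_bad_fit_goes_negative(self):
        assert r2_per_response([1.0, 2.0, 3.0], [1.0, 2.0, 5.0]) == pytest.approx(-1.0)

    def test_constant_observations_flagged(self):
        with pytest.raises(ValueError, match="identical"):
            r2_per_response([2.0, 2.0], [1.0, 2.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            r2_per_response([1.0], [1.0])


class TestFitMultiresponse:
    def test_only_active_constants_are_free(self):
        sc = table1_scenario("Lys-Glu-170")
        ds = generate_dataset(sc.spec, sc.k, NoiseModel(cv=0.0), 1)
        fit = fit_multiresponse(ds, sc.spec, sc.k.scaled(2.0))
        assert set(fit.free_indices) == sc.spec.active_k
        assert {5, 8, 9, 10}.isdisjoint(fit.free_indices)
        # pinned constants stay exactly zero in the estimates
        for i in (5, 8, 9, 10):
            assert fit.estimates[i] == 0.0

    def test_noise_free_self_consistency_within_one_percent(self):
        sc = table1_scenario("Trp-Glu-170")
        fit = refit_from_simulation(sc.spec, sc.k)
        assert fit.converged
        for i in fit.free_indices:
            assert fit.estimates[i] == pytest.approx(sc.k[i], rel=0.01)

    def test_printed_view_consistent_with_natural_estimates(self):
        sc = table1_scenario("Trp-Glu-170")
        fit = refit_from_simulation(sc.spec, sc.k)
        printed = fit.estimates_printed()
        for i in fit.free_indices:
            assert printed[i] == pytest.approx(natural_to_printed(fit.estimates[i], i))

    def test_replicate_averaging_mode(self):
        sc = table1_scenario("Trp-Glu-170")
        ds = generate_dataset(sc.spec, sc.k, NoiseModel(cv=0.05, seed=3), 3)
        fit = fit_multiresponse(ds, sc.spec, sc.k.scaled(2.0), average_replicates=True)
        # replicates collapsed to one mean per (time, species); the five
        # species the Trp system cannot produce are excluded as all-zero
        assert fit.n_obs == 8 * (14 - 5)

    def test_r2_near_one_on_noise_free_data(self):
        sc = table1_scenario("Trp-Glu-170")
        fit = refit_from_simulation(sc.spec, sc.k)
        for species, r2 in fit.per_response_r2.items():
            assert r2 == pytest.approx(1.0, abs=1e-6), species

    def test_nonpositive_start_for_free_constant_rejected(self):
        sc = table1_scenario("Trp-Glu-170")
        ds = generate_dataset(sc.spec, sc.k, NoiseModel(cv=0.0), 1)
        with pytest.raises(ValueError, match="start"):
            fit_multiresponse(ds, sc.spec, RateConstants.zeros())

    def test_fit_eliminations_frees_only_producible_sinks(self):
        sc = table1_scenario("Lys-Glu-170")
        k_true = sc.k.with_values({16: 0.0})
        ds = generate_dataset(sc.spec, k_true, NoiseModel(cv=0.0), 1)
        start = sc.k.scaled(2.0).with_values(
            {i: 0.01 for i in range(12, 19)}
        )
        fit = fit_multiresponse(ds, sc.spec, start, fit_eliminations=True, max_nfev=200)
        # acrylamide/harmane/norharmane are unreachable in Lys/Glu, so their
        # elimination constants (e16, e17, e18) must not be free
        assert {16, 17, 18}.isdisjoint(fit.free_indices)
        assert {12, 13, 14, 15} <= set(fit.free_indices)

    def test_start_robustness_noise_free_is_unimodal(self):
        sc = table1_scenario("Trp-Glu-170")
        ds = generate_dataset(sc.spec, sc.k, NoiseModel(cv=0.0), 1)
        lo, hi = check_start_robustness(ds, sc.spec, sc.k)
        assert not lo.multimodal and not hi.multimodal
        for i in lo.free_indices:
            assert lo.estimates[i] == pytest.approx(hi.estimates[i], rel=1e-6)
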