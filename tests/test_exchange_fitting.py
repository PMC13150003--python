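import math

import numpy as np
import pytest

from r1rho import (
    A2_WT_T9_TRIANGULAR,
    DispersionDataset,
    ExchangeModelSpec,
    FitResult,
    compare_models,
    fit_model,
    information_criteria,
    mc_parameter_errors,
    model_r1rho,
    simulate_dispersion_dataset,
)
from conftest import trott_palmer_r1rho

TWO_STATE = {"kex_ab": 2000.0, "p_b": 0.005, "dw_b": 600.0, "r1": 2.5, "r2": 22.5}


def small_grid():
    import pandas as pd

    rows = [(nu, 0.0) for nu in np.linspace(1000.0, 6000.0, 8)]
    rows += [(250.0, om) for om in np.linspace(-1200.0, 1200.0, 13)]
    return pd.DataFrame(rows, columns=["nu_sl_hz", "offset_hz"])


class TestForwardModel:
    def test_no_minor_population_reduces_to_tilted_frame_form(self):
        params = dict(TWO_STATE, p_b=0.0)
        nus = np.array([250.0, 1000.0])
        oms = np.array([-500.0, 400.0])
        pred = model_r1rho("two_state", params, nus, oms)
        w1 = 2 * np.pi * nus
        obar = 2 * np.pi * (0.0 - oms)
        s2 = w1**2 / (w1**2 + obar**2)
        expected = 2.5 * (1 - s2) + 22.5 * s2
        assert np.allclose(pred, expected, rtol=1e-4)

    def test_triangular_degenerates_to_linear(self):
        tri = dict(A2_WT_T9_TRIANGULAR, kex_ac=1e-9)
        lin = {k: v for k, v in A2_WT_T9_TRIANGULAR.items() if k != "kex_ac"}
        nus = np.array([500.0, 1500.0, 4000.0])
        oms = np.array([0.0, -700.0, 350.0])
        assert np.allclose(
            model_r1rho("triangular", tri, nus, oms),
            model_r1rho("linear", lin, nus, oms),
            atol=1e-6,
        )

    def test_linear_degenerates_to_two_state(self):
        lin = dict(TWO_STATE)
        lin.update({"kex_bc": 1e-9, "p_c": 1e-12, "dw_c": 300.0})
        nus = np.array([500.0, 2000.0])
        oms = np.array([0.0, 450.0])
        assert np.allclose(
            model_r1rho("linear", lin, nus, oms),
            model_r1rho("two_state", TWO_STATE, nus, oms),
            atol=1e-6,
        )

    def test_trott_palmer_agreement(self):
        nus = np.linspace(500.0, 6000.0, 10)
        pred = model_r1rho("two_state", TWO_STATE, nus, np.zeros_like(nus))
        oracle = trott_palmer_r1rho(0.995, 0.005, 600.0, 2000.0, 2.5, 22.5, nus, 0.0)
        assert np.allclose(pred, oracle, rtol=0.02)

    def test_mirror_symmetry(self):
        nus = np.array([300.0, 300.0, 1500.0])
        oms = np.array([-800.0, 650.0, 0.0])
        flipped = dict(A2_WT_T9_TRIANGULAR)
        flipped["dw_b"] = -flipped["dw_b"]
        flipped["dw_c"] = -flipped["dw_c"]
        a = model_r1rho("triangular", A2_WT_T9_TRIANGULAR, nus, oms)
        b = model_r1rho("triangular", flipped, nus, -oms)
        assert np.allclose(a, b, rtol=1e-10)


class TestFitting:
    def test_noise_free_self_consistency(self):
        ds = simulate_dispersion_dataset(
            "two_state", TWO_STATE, grid=small_grid(), noise_pct=0.0, observable_kind="r1rho"
        )
        spec = ExchangeModelSpec("two_state", fixed={"r1": 2.5})
        fit = fit_model(ds, spec, n_starts=8, seed=0)
        assert fit.estimates["kex_ab"] == pytest.approx(2000.0, rel=1e-4)
        assert fit.estimates["p_b"] == pytest.approx(0.005, rel=1e-4)
        assert fit.estimates["dw_b__sim"] == pytest.approx(600.0, rel=1e-4)
        assert fit.estimates["r2__sim"] == pytest.approx(22.5, rel=1e-4)

    def test_identifiability_guard(self):
        ds = simulate_dispersion_dataset(
            "two_state", TWO_STATE, grid=small_grid().head(5), noise_pct=1.0, seed=0
        )
        with pytest.raises(ValueError, match="constrain"):
            fit_model(ds, ExchangeModelSpec("triangular"), n_starts=2, seed=0)

    def test_duplicated_dataset_global_fit_matches_single(self):
        ds = simulate_dispersion_dataset(
            "two_state", TWO_STATE, grid=small_grid(), noise_pct=1.0, seed=3,
            observable_kind="r1rho", spin_label="A",
        )
        twin = DispersionDataset("B", ds.table.copy(), ds.observable_kind)
        spec = ExchangeModelSpec("two_state", fixed={"r1": 2.5})
        single = fit_model(ds, spec, n_starts=6, seed=1)
        double = fit_model([ds, twin], spec, n_starts=6, seed=1)
        assert double.estimates["kex_ab"] == pytest.approx(
            single.estimates["kex_ab"], rel=1e-3
        )
        assert double.chi2 == pytest.approx(2.0 * single.chi2, rel=1e-3)

    def test_monte_carlo_errors_shrink_with_data_sd(self):
        spec = ExchangeModelSpec("two_state", fixed={"r1": 2.5})
        sds = []
        for noise in (0.5, 2.0):
            ds = simulate_dispersion_dataset(
                "two_state", TWO_STATE, grid=small_grid(), noise_pct=noise, seed=4,
                observable_kind="r1rho",
            )
            fit = fit_model(ds, spec, n_starts=6, seed=2)
            fit = mc_parameter_errors(fit, ds, spec, n_replicas=30, seed=5)
            sds.append(fit.mc_sd["kex_ab"])
            # replica scatter should bracket the point estimate
            assert abs(fit.estimates["kex_ab"] - 2000.0) <= 4.0 * fit.mc_sd["kex_ab"]
        assert sds[0] < sds[1]

    def test_monte_carlo_seed_determinism(self):
        spec = ExchangeModelSpec("two_state", fixed={"r1": 2.5})
        ds = simulate_dispersion_dataset(
            "two_state", TWO_STATE, grid=small_grid(), noise_pct=1.0, seed=6,
            observable_kind="r1rho",
        )
        fit = fit_model(ds, spec, n_starts=4, seed=3)
        a = mc_parameter_errors(fit, ds, spec, n_replicas=20, seed=8)
        b = mc_parameter_errors(fit, ds, spec, n_replicas=20, seed=8)
        assert a.mc_sd == b.mc_sd


class TestInformationCriteria:
    def test_hand_computed_case(self):
        # N = 20, k = 4, chi2 = 10
        aicc, bic = information_criteria(10.0, 20, 4)
        aic = 20 * math.log(10.0 / 20.0) + 2 * 4
        assert aicc == pytest.approx(aic + 2 * 4 * 5 / 15, rel=1e-12)
        assert bic == pytest.approx(20 * math.log(0.5) + 4 * math.log(20), rel=1e-12)

    def test_penalty_monotone_in_parameters(self):
        a4 = information_criteria(10.0, 20, 4)
        a6 = information_criteria(10.0, 20, 6)
        assert a6[0] > a4[0] and a6[1] > a4[1]

    def test_small_sample_correction_vanishes(self):
        aicc, _ = information_criteria(100.0, 10**6, 4)
        aic = 10**6 * math.log(100.0 / 10**6) + 8
        assert aicc - aic == pytest.approx(0.0, abs=1e-4)

    def test_undefined_for_tiny_samples(self):
        with pytest.raises(ValueError):
            information_criteria(1.0, 5, 4)


def _dummy_fit(topology, chi2, n_params, n_points=78):
    aicc, bic = information_criteria(chi2, n_points, n_params)
    return FitResult(
        topology=topology, estimates={}, stderr={}, chi2=chi2, n_points=n_points,
        n_params=n_params, aicc=aicc, bic=bic, residuals=np.empty(0),
    )


class TestModelComparison:
    def test_identical_quality_prefers_simpler(self):
        simple = _dummy_fit("two_state", 80.0, 5)
        rich = _dummy_fit("triangular", 80.0, 9)
        cmp = compare_models([rich, simple])
        assert cmp.selected.topology == "two_state"
        assert cmp.justification

    def test_large_improvement_prefers_richer(self):
        simple = _dummy_fit("two_state", 400.0, 5)
        rich = _dummy_fit("triangular", 70.0, 9)
        cmp = compare_models([simple, rich])
        assert cmp.selected.topology == "triangular"
        assert any(ft["p"] < 0.05 for ft in cmp.f_tests)

    def test_partial_evidence_reports_disagreement(self):
        simple = _dummy_fit("two_state", 100.0, 5)
        rich = _dummy_fit("triangular", 74.0, 9)  # F-test passes, BIC gain < 10
        cmp = compare_models([simple, rich])
        assert cmp.selected.topology == "two_state"
        assert cmp.disagreements

    def test_non_nested_equal_size_ranked_by_criteria(self):
        lin = _dummy_fit("linear", 90.0, 8)
        star = _dummy_fit("star", 70.0, 8)
        cmp = compare_models([lin, star])
        assert cmp.selected.topology == "star"

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError):
            compare_models([_dummy_fit("two_state", 10.0, 5, 40), _dummy_fit("linear", 9.0, 8, 50)])
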