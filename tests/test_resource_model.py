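"""Resource-allocation growth model, regulation surface, and two-stage fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from growthfeedback import (HillFitOptions, ModelParams, RescaledParams,
                            build_regulation_surface, drug_free_growth,
                            filter_measurements, free_fola, growth_rate_model,
                            model_dose_response, proteome_fractions,
                            rescaled_growth, rewire_regulation)
from growthfeedback.resource_model import fit_drug_free, fit_drug_response
from growthfeedback.synthetic_data import generate_surface_dataset


@pytest.fixture
def simple_params():
    return ModelParams(omega_R=1.0, omega_C=1.0, K_Mc=0.2, chi_demand=2.0)


class TestCoreEquations:
    def test_proteome_fractions(self, simple_params):
        assert proteome_fractions(0.0, simple_params) == (0.0, 1.0)
        p2 = ModelParams(omega_R=2.0, omega_C=1.0, K_Mc=0.2, chi_demand=2.0)
        phi_r, phi_c = proteome_fractions(0.25, p2)
        assert (phi_r, phi_c) == (0.5, 0.5)
        with pytest.raises(ValueError):
            proteome_fractions(0.6, p2)

    def test_drug_free_growth_form(self, simple_params):
        assert drug_free_growth(0.0, simple_params) == pytest.approx(0.5)
        a = np.linspace(0, 20, 50)
        lam = drug_free_growth(a, simple_params)
        assert np.all(np.diff(lam) < 0)
        # closed-form half-growth limitation: a* = omega_R/omega_C + 1
        a_star = simple_params.omega_R / simple_params.omega_C + 1.0
        assert drug_free_growth(a_star, simple_params) == pytest.approx(
            drug_free_growth(0.0, simple_params) / 2.0, rel=1e-12)
        with pytest.raises(ValueError):
            drug_free_growth(-1.0, simple_params)

    def test_free_fola_binding(self):
        assert free_fola(3.0, 0.0, 0.2) == pytest.approx(3.0)
        assert free_fola(3.0, 0.2, 0.2) == pytest.approx(1.5)
        # equilibrium identity: [free][TMP]/[bound] = K_Mc
        chi, c, kmc = 5.0, 0.7, 0.13
        free = free_fola(chi, c, kmc)
        bound = chi - free
        assert free * c / bound == pytest.approx(kmc, rel=1e-12)

    def test_growth_model_regimes_and_kink(self, simple_params):
        p = simple_params
        lam0 = drug_free_growth(1.0, p)
        # ribosome-limited: enough free enzyme, drug has no effect
        c = 0.3
        chi_enough = p.chi_demand * (1 + c / p.K_Mc) * 1.01
        assert growth_rate_model(1.0, c, chi_enough, p) == pytest.approx(lam0)
        # enzyme-limited at zero dose: half the demand gives half the growth
        assert growth_rate_model(1.0, 0.0, p.chi_demand / 2, p) == pytest.approx(
            lam0 / 2)
        # kink located at c* = K_Mc (chi/chi_demand - 1); flat before,
        # strictly decreasing after (dense scan)
        chi = 1.5 * p.chi_demand
        c_star = p.K_Mc * (chi / p.chi_demand - 1.0)
        c_grid = np.linspace(0, 3 * c_star, 301)
        lam = growth_rate_model(np.ones_like(c_grid), c_grid, chi, p)
        before = c_grid <= c_star
        assert np.allclose(lam[before], lam0, rtol=1e-12)
        after = lam[~before]
        assert np.all(np.diff(after) < 0)

    def test_growth_non_increasing_in_limitation(self, simple_params):
        a = np.linspace(0, 15, 60)
        lam = growth_rate_model(a, 0.1, 1.5, simple_params)
        assert np.all(np.diff(lam) <= 1e-15)


class TestRescaling:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.2, 3.0), st.floats(0.05, 5.0), st.floats(0.01, 2.0),
           st.floats(0.1, 10.0))
    def test_dimensional_rescaled_equivalence(self, omega_r, ratio, kmc, chix):
        params = ModelParams(omega_R=omega_r, omega_C=ratio * omega_r,
                             K_Mc=kmc, chi_demand=chix)
        rs = params.rescaled()
        a = np.linspace(0, 10, 20)[:, None, None]
        c = np.linspace(0, 5 * kmc, 20)[None, :, None]
        chi = np.linspace(0, 3 * chix, 5)[None, None, :]
        lam = growth_rate_model(a, c, chi, params)
        lam_bar = rescaled_growth(a, c / kmc, chi / chix, rs.A)
        assert np.allclose(lam, lam_bar / omega_r, rtol=1e-12, atol=1e-15)

    def test_roundtrip_exact(self):
        params = ModelParams(0.4, 0.9, 0.05, 3.0)
        back = params.rescaled().dimensional()
        assert back == params

    def test_shared_a_gives_identical_surfaces(self):
        p1 = ModelParams(0.5, 1.0, 0.2, 1.0)
        p2 = ModelParams(1.5, 3.0, 0.6, 2.0)  # same A = 2
        a = np.linspace(0, 8, 15)
        c_bar = np.linspace(0, 6, 15)
        lam1 = rescaled_growth(a[:, None], c_bar[None, :], 1.4, p1.rescaled().A)
        lam2 = rescaled_growth(a[:, None], c_bar[None, :], 1.4, p2.rescaled().A)
        assert np.array_equal(lam1, lam2)


def plane_records():
    rows = [(a, c, 0.5, (10.0 - a) + 5.0 * c)
            for a in (0.0, 2.5, 5.0, 10.0) for c in (0.0, 0.2, 0.4)]
    return pd.DataFrame(rows, columns=["a", "c", "growth", "expression"])


class TestRegulationSurface:
    def test_exact_plane_interpolation(self):
        surface = build_regulation_surface(plane_records())
        assert surface.evaluate(2.5, 0.2) == pytest.approx(8.5, rel=1e-12)
        assert surface.evaluate(7.5, 0.0) == pytest.approx(2.5, rel=1e-12)

    def test_clamp_above_convergence_concentration(self):
        surface = build_regulation_surface(plane_records())
        for a in (0.0, 1.3, 5.0, 10.0):
            assert surface.evaluate(a, 0.9) == surface.evaluate(a, 0.4)
            assert surface.evaluate(a, 2.0) == surface.evaluate(a, 0.4)

    def test_zero_residual_on_linear_data(self):
        surface = build_regulation_surface(plane_records())
        df = plane_records()
        pred = surface.evaluate(df["a"].to_numpy(), df["c"].to_numpy())
        assert np.allclose(pred, df["expression"], rtol=1e-12)

    def test_replicate_weighting_matches_normal_equations(self):
        df = plane_records()
        extra = pd.DataFrame([(0.0, 0.2, 0.5, 20.0)], columns=df.columns)
        df2 = pd.concat([df, extra], ignore_index=True)
        surface = build_regulation_surface(df2)
        # oracle: equally-weighted normal equations at node a=0
        sub = df2[(df2["a"] == 0.0) & (df2["c"] <= 0.4)]
        x, y = sub["c"].to_numpy(), sub["expression"].to_numpy()
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert surface.evaluate(0.0, 0.0) == pytest.approx(beta[0], rel=1e-10)
        assert surface.evaluate(0.0, 0.4) == pytest.approx(
            beta[0] + 0.4 * beta[1], rel=1e-10)

    def test_single_concentration_node_rejected(self):
        df = pd.DataFrame([(0.0, 0.1, 0.5, 1.0), (0.0, 0.1, 0.5, 1.1),
                           (2.5, 0.0, 0.5, 1.0), (2.5, 0.2, 0.5, 1.2)],
                          columns=["a", "c", "growth", "expression"])
        with pytest.raises(ValueError, match="fewer than 2"):
            build_regulation_surface(df)

    def test_extrapolation_refused_by_default(self):
        surface = build_regulation_surface(plane_records())
        with pytest.raises(ValueError, match="hull"):
            surface.evaluate(12.0, 0.1)


class TestFilter:
    def test_filter_rules(self):
        df = pd.DataFrame([
            (12.0, 0.1, 0.5, 100.0),   # a too large
            (5.0, 0.1, 0.04, 100.0),   # too slow
            (5.0, 0.1, 0.5, 0.0),      # zero fluorescence
            (5.0, 0.1, 0.5, 1.0),      # passes
            (10.0, 0.1, 0.05, 1.0),    # boundary values pass
        ], columns=["a", "c", "growth", "expression"])
        out = filter_measurements(df)
        assert list(out["passes_filter"]) == [False, False, False, True, True]
        assert len(out) == len(df)  # flagged, never dropped


class TestTwoStageFit:
    def test_drug_free_recovery_noiseless(self):
        truth = ModelParams(0.5, 0.3, 0.2, 1.0)
        a = np.array([0.0, 1.0, 2.0, 5.0, 10.0])
        df = pd.DataFrame({"a": a, "c": 0.0,
                           "growth": drug_free_growth(a, truth),
                           "expression": 1.0})
        fit = fit_drug_free(df)
        assert fit.omega_R == pytest.approx(0.5, rel=1e-8)
        assert fit.omega_C == pytest.approx(0.3, rel=1e-8)
        # duplication invariance
        fit2 = fit_drug_free(pd.concat([df, df], ignore_index=True))
        assert fit2.omega_R == pytest.approx(fit.omega_R, rel=1e-10)

    def test_drug_free_noisy_matches_grid_search_oracle(self):
        rng = np.random.default_rng(2)
        truth = ModelParams(0.5, 0.3, 0.2, 1.0)
        a = np.repeat([0.0, 1.0, 2.0, 5.0, 10.0], 4)
        g = drug_free_growth(a, truth) * rng.lognormal(0, 0.05, len(a))
        df = pd.DataFrame({"a": a, "c": 0.0, "growth": g, "expression": 1.0})
        fit = fit_drug_free(df)
        wr_grid = np.linspace(0.3, 0.8, 400)
        wc_grid = np.linspace(0.1, 0.6, 400)
        sse = [(np.sum((1.0 / (wr + wc * (a + 1)) - g) ** 2), wr, wc)
               for wr in wr_grid for wc in wc_grid]
        _, wr_best, wc_best = min(sse)
        assert abs(fit.omega_R - wr_best) < (wr_grid[1] - wr_grid[0])
        assert abs(fit.omega_C - wc_best) < (wc_grid[1] - wc_grid[0])

    def test_drug_response_self_consistency(self, wt_surface, params):
        df = filter_measurements(generate_surface_dataset(
            wt_surface, params, n_replicates=1, noise_cv=0.0))
        stage1 = fit_drug_free(df)
        fit = fit_drug_response(df, stage1.omega_R, stage1.omega_C, wt_surface,
                                seed=0)
        assert fit.K_Mc == pytest.approx(params.K_Mc, rel=1e-6)
        assert fit.chi_demand == pytest.approx(params.chi_demand, rel=1e-6)

    def test_expression_unit_invariance(self, wt_surface, params):
        """Only chi/chi_demand enters growth: doubling the surface units and
        the demand leaves the predicted K_Mc unchanged and doubles chi_X."""
        from growthfeedback import RegulationSurface
        df = filter_measurements(generate_surface_dataset(
            wt_surface, params, n_replicates=1, noise_cv=0.0))
        doubled = RegulationSurface(wt_surface.a_nodes,
                                    wt_surface.intercepts * 2,
                                    wt_surface.slopes * 2,
                                    clamp_c=wt_surface.clamp_c)
        stage1 = fit_drug_free(df)
        fit = fit_drug_response(df, stage1.omega_R, stage1.omega_C, doubled,
                                seed=0)
        assert fit.K_Mc == pytest.approx(params.K_Mc, rel=1e-5)
        assert fit.chi_demand == pytest.approx(2 * params.chi_demand, rel=1e-5)

    def test_unidentifiable_when_all_unaffected(self, wt_surface):
        # enormous binding constant: no record leaves the ribosome-limited
        # regime, so the demand cannot be identified
        weak = ModelParams(0.5, 0.5, 1e6, 1.0)
        df = filter_measurements(generate_surface_dataset(
            wt_surface, weak, n_replicates=1, noise_cv=0.0))
        stage1 = fit_drug_free(df)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_drug_response(df, stage1.omega_R, stage1.omega_C, wt_surface,
                              seed=0)


class TestRewiring:
    def test_constant_mode(self, wt_surface):
        chi1 = wt_surface.evaluate(0.0, 1.0)
        const = rewire_regulation(wt_surface, "constant")
        for a, c in [(0.0, 0.0), (5.0, 0.3), (10.0, 2.0)]:
            assert const.evaluate(a, c) == pytest.approx(chi1, rel=1e-12)

    def test_inverted_mode(self, wt_surface):
        chi1 = wt_surface.evaluate(0.0, 1.0)
        inv = rewire_regulation(wt_surface, "inverted")
        assert inv.evaluate(0.0, 0.0) == pytest.approx(2 * chi1, rel=1e-12)
        assert inv.evaluate(0.0, 0.5) == pytest.approx(1.5 * chi1, rel=1e-12)
        assert inv.evaluate(0.0, 1.0) == pytest.approx(chi1, rel=1e-12)
        assert inv.evaluate(0.0, 2.0) == pytest.approx(chi1, rel=1e-12)

    def test_wildtype_mode_returns_surface(self, wt_surface):
        assert rewire_regulation(wt_surface, "wildtype") is wt_surface


class TestModelDoseResponse:
    def test_expression_at_demand_gives_unit_hill_curve(self):
        """With expression pinned exactly at the demand the model curve is
        lambda0/(1 + c/K_Mc): a Hill curve with n = 1 and IC50 = K_Mc."""
        from growthfeedback import RegulationSurface
        params = ModelParams(0.5, 0.5, 0.2, 1.0)
        surface = RegulationSurface([0.0, 10.0], [1.0, 1.0], [0.0, 0.0])
        c_grid = np.concatenate([[0.0], np.logspace(-2.5, 1.2, 16)])
        curve, fit = model_dose_response(params, surface, 0.0, c_grid)
        expected = drug_free_growth(0.0, params) / (1 + c_grid / 0.2)
        assert np.allclose(curve.growth, expected, rtol=1e-12)
        assert fit.n == pytest.approx(1.0, abs=1e-4)
        assert fit.ic50 == pytest.approx(0.2, rel=1e-3)

    def test_feedback_flattens_relative_to_constant(self, wt_surface, params,
                                                    sensitivity_chain):
        assert sensitivity_chain["n_wildtype"] < sensitivity_chain["n_constant"]

    def test_narrow_grid_warns(self, wt_surface, params):
        with pytest.warns(UserWarning, match="too narrow"):
            model_dose_response(params, wt_surface, 0.0,
                                np.linspace(0.0, 0.1, 6))
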