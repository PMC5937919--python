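"""Flux estimation, goodness of fit, scenarios, diagnostics, contributions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fluxmu as fm
from fluxmu.errors import InsufficientDataError, ScenarioError

from .conftest import FIXED_EXCHANGES, MEASURED_POOLS


@pytest.fixture(scope="module")
def toy_network():
    """Two converging branches: X is a flux-weighted blend of labeled A and
    unlabeled B, so the branch split is read off X's M+1 fraction."""
    rxns = [
        fm.parse_equation("IN_A", "A.ext (a) -> X (a)", reversible=False),
        fm.parse_equation("IN_B", "B.ext (a) -> X (a)", reversible=False),
        fm.Reaction("OUT", (("X", "a"),), (("P", "a"),), reversible=False, basis=True),
    ]
    return fm.FluxNetwork(rxns, preferred_free=["IN_A", "OUT"])


@pytest.fixture(scope="module")
def toy_tracer():
    return fm.TracerSpec({"A.ext": (1.0,), "B.ext": (0.0,)})


class TestFitFluxes:
    def test_zero_noise_parameter_recovery(self, noise_free_fit, noise_free_measurements):
        _, true_nets, true_exch = noise_free_measurements
        assert noise_free_fit.ssr < 1e-6
        for rxn, truth in true_nets.items():
            assert noise_free_fit.nets[rxn] == pytest.approx(truth, rel=1e-4, abs=1e-6)

    def test_toy_matches_grid_search_oracle(self, toy_network, toy_tracer):
        meas = fm.MeasurementSet.from_ifs({"X": np.array([0.7, 0.3])}, 0.05)
        fit = fm.fit_fluxes(toy_network, meas, toy_tracer, restarts=3, seed=0)

        grid = np.linspace(0, 1, 20_001)
        ssr = ((grid - 0.3) / 0.05) ** 2 + (((1 - grid) - 0.7) / 0.05) ** 2
        best = grid[np.argmin(ssr)]
        assert fit.nets["IN_A"] == pytest.approx(best, abs=1e-4)
        assert fit.nets["IN_B"] == pytest.approx(1 - best, abs=1e-4)

    def test_uniform_sd_scaling_identity(self, network, reference_experiment):
        """x10 on every SD: same optimum, SSR / 100."""
        meas, _, _ = fm.measurement_set_from_scenario(
            reference_experiment, network, MEASURED_POOLS, noise=True, seed=21
        )
        scaled = meas.copy()
        scaled.data["sd"] *= 10
        kw = dict(restarts=1, seed=0, fixed_exchanges=FIXED_EXCHANGES)
        f1 = fm.fit_fluxes(network, meas, reference_experiment.tracer, **kw)
        f2 = fm.fit_fluxes(network, scaled, reference_experiment.tracer, **kw)
        assert f2.nets["G6PDH"] == pytest.approx(f1.nets["G6PDH"], abs=1e-5)
        assert f2.ssr == pytest.approx(f1.ssr / 100, rel=1e-3)

    def test_no_included_measurements(self, toy_network, toy_tracer):
        meas = fm.MeasurementSet.from_ifs({"X": np.array([0.7, 0.3])}, 0.05)
        meas.data["include"] = False
        with pytest.raises(InsufficientDataError):
            fm.fit_fluxes(toy_network, meas, toy_tracer)

    def test_seed_determinism(self, toy_network, toy_tracer):
        meas = fm.MeasurementSet.from_ifs({"X": np.array([0.6, 0.4])}, 0.02)
        a = fm.fit_fluxes(toy_network, meas, toy_tracer, restarts=4, seed=9)
        b = fm.fit_fluxes(toy_network, meas, toy_tracer, restarts=4, seed=9)
        np.testing.assert_array_equal(a.theta, b.theta)


class TestChi2:
    def test_critical_value_dof_10(self):
        passed, crit = fm.chi2_gof(10.0, 20, 10)
        assert crit == pytest.approx(18.307, abs=1e-3)
        assert passed

    def test_zero_ssr_always_passes(self):
        assert fm.chi2_gof(0.0, 5, 1)[0]

    def test_nonpositive_dof(self):
        with pytest.raises(ValueError):
            fm.chi2_gof(1.0, 3, 3)

    def test_fit_reports_chi2_fields(self, noisy_fit):
        _, fit = noisy_fit
        assert fit.dof == fit.residuals.shape[0] - len(
            set(fit.residuals["metabolite"])
        ) - fit.n_free
        assert fit.ssr >= 0
        assert fit.chi2_critical == pytest.approx(
            stats.chi2.ppf(0.95, fit.dof), rel=1e-12
        )


class TestScenarioEngine:
    def _toy_meas(self):
        return fm.MeasurementSet.from_ifs(
            {"M": np.array([0.50, 0.45, 0.03, 0.015, 0.005])}, 0.01
        )

    def test_abundance_mask(self):
        out = fm.scenario_engine(self._toy_meas(), fm.ScenarioSpec(abundance_threshold=0.02))
        assert out.data["include"].tolist() == [True, True, True, False, False]

    def test_sd_inflation_with_overrides(self):
        spec = fm.ScenarioSpec(
            abundance_threshold=None, sd_inflation=3.0, keep_analytical=(("M", 1),)
        )
        out = fm.scenario_engine(self._toy_meas(), spec)
        eff = out.effective_sd()
        assert eff[0] == pytest.approx(0.03)
        assert eff[1] == pytest.approx(0.01)  # kept at analytical precision

    def test_empty_scenario_rejected(self):
        with pytest.raises(ScenarioError):
            fm.scenario_engine(self._toy_meas(), fm.ScenarioSpec(abundance_threshold=0.9))

    def test_masked_entries_leave_ssr(self, network, reference_experiment):
        """Removing measurements can only lower the attainable optimum."""
        meas, _, _ = fm.measurement_set_from_scenario(
            reference_experiment, network, MEASURED_POOLS, noise=True, seed=33
        )
        masked = fm.scenario_engine(meas, fm.ScenarioSpec(abundance_threshold=0.02))
        kw = dict(restarts=1, seed=0, fixed_exchanges=FIXED_EXCHANGES)
        full = fm.fit_fluxes(network, meas, reference_experiment.tracer, **kw)
        sub = fm.fit_fluxes(network, masked, reference_experiment.tracer, **kw)
        assert sub.ssr <= full.ssr + 1e-9


class TestDiagnostics:
    def test_well_specified_fit_residuals(self, noisy_fit):
        _, fit = noisy_fit
        d = fm.residual_diagnostics(fit)
        n = d.residuals.size
        assert abs(d.mean) < 3 / np.sqrt(n)
        assert d.sd == pytest.approx(1.0, abs=0.35)
        assert d.shapiro_p > 0.01
        assert d.plotting_positions.shape == d.ordered_residuals.shape

    def test_shapiro_calibration_on_normal_draws(self):
        """Shapiro-Wilk at alpha=0.05 rejects ~5% of well-behaved batches."""
        rng = np.random.default_rng(17)
        rejections = sum(
            fm.residual_diagnostics(rng.normal(size=50)).shapiro_p < 0.05
            for _ in range(200)
        )
        assert 2 <= rejections <= 22  # 3-sigma binomial band around 10

    def test_too_few_residuals(self):
        with pytest.raises(InsufficientDataError):
            fm.residual_diagnostics(np.array([0.1, -0.1]))

    def test_constant_residuals(self):
        with pytest.raises(ValueError, match="constant"):
            fm.residual_diagnostics(np.ones(10))


class TestContributionMatrix:
    def test_columns_sum_to_100(self, noisy_fit):
        _, fit = noisy_fit
        cm = fm.contribution_matrix(fit)
        sums = cm.sum(axis=0)
        assert np.all(np.abs(sums - 100.0) < 2.0)
        assert cm.shape == (fit.residuals.shape[0], len(fit.param_names))
        assert np.all(cm.to_numpy() >= 0)

    def test_single_measurement_single_flux(self, toy_network, toy_tracer):
        meas = fm.MeasurementSet.from_ifs({"X": np.array([0.7, 0.3])}, 0.05)
        fit = fm.fit_fluxes(toy_network, meas, toy_tracer, restarts=2, seed=0)
        cm = fm.contribution_matrix(fit)
        # the two closure-coupled entries of X split the single flux 50/50
        assert cm["net IN_A"].sum() == pytest.approx(100.0)
        np.testing.assert_allclose(cm["net IN_A"], [50.0, 50.0], atol=1e-6)

    def test_matches_sd_perturbation_brute_force(self, noisy_fit):
        """Share_jm predicts the flux-variance change when sd_m is nudged."""
        meas, fit = noisy_fit
        J = fit.jacobian
        C = np.linalg.inv(J.T @ J)
        cm = fm.contribution_matrix(fit)
        eps = 0.01
        for m in (0, 5, 11):
            scale = np.ones(J.shape[0])
            scale[m] = 1.0 / (1.0 + eps)  # inflate sd_m by (1+eps)
            Jp = J * scale[:, None]
            Cp = np.linalg.inv(Jp.T @ Jp)
            for j, name in enumerate(fit.param_names):
                dvar = Cp[j, j] - C[j, j]
                predicted = cm.iloc[m, j] / 100.0 * C[j, j] * ((1 + eps) ** 2 - 1)
                if predicted > 1e-12 * C[j, j]:
                    assert dvar == pytest.approx(predicted, rel=0.1)


class TestConfidenceIntervals:
    def test_ci_contains_point_and_is_deterministic(
        self, network, reference_experiment, noisy_fit
    ):
        meas, fit = noisy_fit
        kw = dict(n_samples=40, seed=5)
        a = fm.mc_confidence_intervals(network, meas, reference_experiment.tracer, fit, **kw)
        b = fm.mc_confidence_intervals(network, meas, reference_experiment.tracer, fit, **kw)
        pd.testing.assert_frame_equal(a.table, b.table)
        for rxn in ("net G6PDH", "net PGI", "net GAPDH"):
            row = a.table.loc[rxn]
            assert row["lo"] - 1e-9 <= row["point"] <= row["hi"] + 1e-9
        assert a.n_failed <= 8


class TestFluxEstimatorAPI:
    def test_sklearn_protocol_and_fit(self, network, reference_experiment, noise_free_measurements):
        from sklearn.base import clone

        meas, true_nets, _ = noise_free_measurements
        est = fm.FluxEstimator(
            network, reference_experiment.tracer, restarts=2, seed=0,
            fixed_exchanges=FIXED_EXCHANGES,
        )
        clone(est)  # get_params/set_params round trip
        est.fit(meas)
        assert est.fluxes_["G6PDH"] == pytest.approx(true_nets["G6PDH"], abs=1e-4)
        pred = est.predict()
        assert set(pred["metabolite"]) == set(MEASURED_POOLS)
        merged = pred.merge(
            meas.data, left_on=["metabolite", "iso"], right_on=["metabolite", "iso"]
        )
        np.testing.assert_allclose(merged["if_sim"], merged["value"], atol=1e-5)

    def test_scenario_applied_inside_estimator(self, network, reference_experiment):
        meas, _, _ = fm.measurement_set_from_scenario(
            reference_experiment, network, MEASURED_POOLS, noise=True, seed=44
        )
        est = fm.FluxEstimator(
            network,
            reference_experiment.tracer,
            restarts=1,
            seed=0,
            scenario=fm.ScenarioSpec(abundance_threshold=0.02),
            fixed_exchanges=FIXED_EXCHANGES,
        )
        est.fit(meas)
        assert est.measurements_.included["value"].min() >= 0.02
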