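import numpy as np
import pytest
import scipy.integrate
import scipy.stats

import bymgamma as bg
from bymgamma.model import (
    ModelSpec,
    ModelState,
    linear_predictor,
    log_prior,
    log_prior_components,
)


class TestGammaLoglik:
    def test_exponential_closed_form(self):
        # shape 1, mean 1 is Exponential(1): log f(1) = -1
        assert bg.gamma_loglik(1.0, 1.0, 1.0) == pytest.approx(-1.0)

    def test_matches_scipy_on_grid(self):
        ys = np.array([0.1, 0.5, 1.0, 3.0, 20.0])
        mus = np.array([0.2, 1.0, 5.0])
        alphas = np.array([0.5, 2.0, 50.0])
        for mu in mus:
            for a in alphas:
                ours = bg.gamma_loglik(ys, mu, a)
                ref = scipy.stats.gamma.logpdf(ys, a, scale=mu / a)
                np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_density_integrates_to_one(self):
        val, _ = scipy.integrate.quad(
            lambda y: np.exp(bg.gamma_loglik(y, 2.0, 3.0)), 0, np.inf
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_mean_parameterisation_by_monte_carlo(self):
        rng = np.random.default_rng(123)
        draws = rng.gamma(2.0, 5.0 / 2.0, 1_000_000)  # shape 2, mean 5
        assert draws.mean() == pytest.approx(5.0, abs=0.01)

    def test_nonpositive_arguments_rejected(self):
        for bad in [(0.0, 1, 1), (1, -1, 1), (1, 1, 0)]:
            with pytest.raises(ValueError):
                bg.gamma_loglik(*bad)


class TestLinearPredictor:
    def test_all_zero_gives_unit_mean(self):
        eta = linear_predictor({"smoking_rate": 25.0}, {"intercept": 0.0}, {})
        assert eta == 0.0 and np.exp(eta) == 1.0

    def test_exposure_only_arithmetic(self):
        eta = linear_predictor(
            {"smoking_rate": 25.0},
            {"intercept": 0.0, "smoking_rate": 0.01165},
            {},
        )
        assert eta == pytest.approx(0.29125)

    def test_intercept_and_structured_effect_trade_off(self):
        row = {"smoking_rate": 10.0}
        coef = {"intercept": 1.0, "smoking_rate": 0.02}
        base = linear_predictor(row, coef, {"u": 0.3})
        shifted = linear_predictor(
            row, {**coef, "intercept": 1.0 - 0.3}, {"u": 0.3 + 0.3}
        )
        # adding c to u and subtracting c from the intercept cannot change
        # eta: the level is confounded, motivating the sum-to-zero constraint
        assert shifted == pytest.approx(base)

    def test_missing_covariate_named_in_error(self):
        with pytest.raises(KeyError, match="mean_bmi"):
            linear_predictor({"smoking_rate": 1.0},
                             {"intercept": 0.0, "mean_bmi": 0.1}, {})


@pytest.fixture
def tiny_state(path_graph):
    icar = bg.build_icar_structure(path_graph)
    state = ModelState(
        beta=np.array([0.5, 0.01]),
        u=np.array([0.2, -0.1, -0.1]),
        v=np.array([0.3, 0.0, -0.2]),
        b=np.array([0.01, -0.02, 0.005]),
        tau_u=2.0, tau_v=3.0, tau_b=4.0, alpha=10.0,
    )
    return state, ModelSpec(confounders=(), year_term=False), icar


class TestLogPrior:
    def test_precision_prior_is_exponential_closed_form(self, tiny_state):
        state, spec, icar = tiny_state
        state.tau_u = 1.0
        comps = log_prior_components(state, spec, icar)
        assert comps["tau_u"] == pytest.approx(np.log(5e-5) - 5e-5)

    def test_blocks_match_independent_densities(self, tiny_state):
        state, spec, icar = tiny_state
        comps = log_prior_components(state, spec, icar)
        assert comps["iid_v"] == pytest.approx(
            scipy.stats.norm.logpdf(state.v, scale=1 / np.sqrt(state.tau_v)).sum()
        )
        assert comps["iid_b"] == pytest.approx(
            scipy.stats.norm.logpdf(state.b, scale=1 / np.sqrt(state.tau_b)).sum()
        )
        assert comps["fixed"] == pytest.approx(
            scipy.stats.norm.logpdf(state.beta, scale=1 / np.sqrt(0.001)).sum()
        )
        assert comps["tau_b"] == pytest.approx(
            scipy.stats.gamma.logpdf(state.tau_b, 1.0, scale=1 / 5e-5)
        )
        assert comps["alpha"] == pytest.approx(
            scipy.stats.gamma.logpdf(state.alpha, 1.0, scale=1 / 0.01)
        )
        # ICAR kernel: (rank/2) log tau - tau/2 * u'Qu
        quad = bg.icar_quadratic_form(icar, state.u)
        assert comps["icar_u"] == pytest.approx(
            0.5 * icar.rank * np.log(state.tau_u) - 0.5 * state.tau_u * quad
        )

    def test_total_is_sum_of_blocks(self, tiny_state):
        state, spec, icar = tiny_state
        comps = log_prior_components(state, spec, icar)
        assert log_prior(state, spec, icar) == pytest.approx(sum(comps.values()))

    def test_doubling_v_changes_only_its_block(self, tiny_state):
        state, spec, icar = tiny_state
        before = log_prior_components(state, spec, icar)
        state.v = 2 * state.v
        after = log_prior_components(state, spec, icar)
        expected = -0.5 * state.tau_v * (np.sum(state.v**2) - np.sum((state.v / 2) ** 2))
        assert after["iid_v"] - before["iid_v"] == pytest.approx(expected)
        for k in before:
            if k != "iid_v":
                assert after[k] == before[k]

    def test_sum_to_zero_violation_rejected(self, tiny_state):
        state, spec, icar = tiny_state
        state.u = state.u + 1e-3
        with pytest.raises(ValueError, match="sum-to-zero"):
            log_prior(state, spec, icar)

    def test_nonpositive_hyperparameters_rejected(self, tiny_state):
        state, spec, icar = tiny_state
        state.tau_v = -1.0
        with pytest.raises(ValueError):
            log_prior(state, spec, icar)


class TestModelSpec:
    def test_exposure_cannot_also_be_confounder(self):
        with pytest.raises(ValueError):
            ModelSpec(exposure="mean_bmi")

    def test_coefficient_order(self):
        spec = ModelSpec(outcome="angina", exposure="passive_home_rate")
        assert spec.coef_names == (
            "intercept", "passive_home_rate", "mean_bmi", "drinking_rate", "year_centered"
        )

    def test_yaml_round_trip(self, tmp_path):
        spec = ModelSpec(outcome="stroke", exposure="passive_work_rate",
                         nonpositive_policy="half_min")
        p = tmp_path / "spec.yaml"
        spec.to_yaml(p)
        assert ModelSpec.from_yaml(p) == spec


class TestSpatialGammaModel:
    def test_loglike_matches_direct_sum(self, small_panel, small_config):
        model = bg.SpatialGammaModel(
            small_panel, small_config.resolve_graph(), small_config.model_spec()
        )
        state = model.initial_state()
        mu = np.exp(model.eta(state))
        direct = scipy.stats.gamma.logpdf(model.y, state.alpha, scale=mu / state.alpha).sum()
        assert model.loglike(state) == pytest.approx(direct)

    def test_nonpositive_cells_dropped_with_warning(self, small_panel, small_config):
        panel = bg.RegionYearPanel(
            small_panel.prevalence.copy(), small_panel.covariates.copy()
        )
        idx = panel.prevalence.query("outcome == 'stroke'").index[0]
        panel.prevalence.loc[idx, "prevalence"] = 0.0
        with pytest.warns(UserWarning, match="nonpositive"):
            model = bg.SpatialGammaModel(
                panel, small_config.resolve_graph(), small_config.model_spec()
            )
        assert model.n_obs == len(panel.prevalence.query("outcome == 'stroke'")) - 1

    def test_half_min_imputation_policy(self, small_panel, small_config):
        panel = bg.RegionYearPanel(
            small_panel.prevalence.copy(), small_panel.covariates.copy()
        )
        idx = panel.prevalence.query("outcome == 'stroke'").index[0]
        panel.prevalence.loc[idx, "prevalence"] = 0.0
        spec = small_config.model_spec(nonpositive_policy="half_min")
        model = bg.SpatialGammaModel(panel, small_config.resolve_graph(), spec)
        assert model.n_obs == len(panel.prevalence.query("outcome == 'stroke'"))
        assert model.y.min() > 0

    def test_region_missing_from_graph_rejected(self, small_panel):
        small_graph = bg.lattice_graph(2, 2)  # does not cover the panel
        with pytest.raises(ValueError, match="absent from graph"):
            bg.SpatialGammaModel(small_panel, small_graph, ModelSpec())
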