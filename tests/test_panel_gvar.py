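"""Panel GVAR: implied moments, FIML oracle agreement, gradient
exactness, prune/step-up behaviour and fit indices."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from famnet.panel_gvar import (
    EdgeConstraintSet, PanelGVARParams, _group_patterns, _loglik_grad_core,
    _pack, _param_index, fiml_loglik, fit_indices, fit_panel_gvar,
    implied_moments, model_selection_pipeline, prune, stepup,
)
from famnet.synthetic_data import FamilyPanelSpec, make_gvar_truth, simulate_panel


@pytest.fixture(scope="module")
def small_params():
    names = ["x0", "x1", "x2"]
    B = np.array([[0.3, 0.1, 0.0], [0.05, 0.25, -0.1], [0.0, 0.1, 0.2]])
    Kw = np.array([[1.2, 0.2, 0.0], [0.2, 1.0, -0.15], [0.0, -0.15, 0.9]])
    Kb = np.array([[1.5, 0.1, 0.05], [0.1, 1.3, 0.0], [0.05, 0.0, 1.1]])
    return PanelGVARParams(names, np.array([0.5, -0.2, 0.1]), B, Kw, Kb)


def _simulate_wide(params, n, W, rng, miss=0.0):
    mean, Sigma = implied_moments(params, W)
    Y = mean + rng.standard_normal((n, W * params.n_nodes)) @ np.linalg.cholesky(Sigma).T
    if miss > 0:
        p = params.n_nodes
        mask = rng.random((n, W * p)) > miss
        for f in range(n):
            if mask[f].reshape(W, p).any(axis=1).sum() < 2:
                mask[f, :2 * p] = True
        Y = np.where(mask, Y, np.nan)
    return Y


class TestImpliedMoments:
    def test_one_node_closed_form(self):
        t = make_gvar_truth(n_nodes_per_member={"child": 1}, autoregression=0.5,
                            between_variance=0.0, contemporaneous_cor=0.0)
        _, S = implied_moments(t, 3)
        assert S[0, 0] == pytest.approx(4 / 3)
        assert S[0, 1] == pytest.approx(2 / 3)
        assert S[0, 2] == pytest.approx(1 / 3)

    def test_no_dynamics_no_intercept_is_block_diagonal(self):
        t = make_gvar_truth(n_nodes_per_member={"child": 2}, autoregression=0.0,
                            between_variance=0.0)
        _, S = implied_moments(t, 3)
        for s in range(3):
            for u in range(3):
                blk = S[2 * s:2 * s + 2, 2 * u:2 * u + 2]
                if s == u:
                    assert np.allclose(blk, t.sigma_zeta)
                else:
                    assert np.allclose(blk, 0)

    def test_nonstationary_rejected(self, small_params):
        bad = PanelGVARParams(small_params.node_names, small_params.mu,
                              1.1 * np.eye(3), small_params.K_within,
                              small_params.K_between)
        with pytest.raises(ValueError):
            implied_moments(bad, 3)

    def test_matches_monte_carlo_panel(self):
        t = make_gvar_truth(n_nodes_per_member={"child": 2, "mother": 1},
                            cross_member_paths=[("m_0", "c_0", 0.2)],
                            autoregression=0.4)
        spec = FamilyPanelSpec(n_families=100_000, n_waves=3, seed=17)
        wide = simulate_panel(t, spec, burn_in=50).to_wide().to_numpy()
        m, S = implied_moments(t, 3)
        assert np.abs(wide.mean(axis=0) - m).max() < 0.03
        assert np.abs(np.cov(wide, rowvar=False) - S).max() < 0.03


class TestFIMLLoglik:
    def test_complete_data_equals_stacked_mvn(self, small_params):
        rng = np.random.default_rng(0)
        Y = _simulate_wide(small_params, 25, 3, rng)
        mean, Sigma = implied_moments(small_params, 3)
        want = multivariate_normal.logpdf(Y, mean, Sigma).sum()
        assert fiml_loglik(small_params, Y) == pytest.approx(want, abs=1e-8)

    def test_missingness_matches_per_family_marginals(self, small_params):
        rng = np.random.default_rng(1)
        Y = _simulate_wide(small_params, 40, 4, rng, miss=0.25)
        mean, Sigma = implied_moments(small_params, 4)
        want = 0.0
        for f in range(len(Y)):
            ix = np.where(~np.isnan(Y[f]))[0]
            want += multivariate_normal.logpdf(Y[f, ix], mean[ix],
                                               Sigma[np.ix_(ix, ix)])
        assert fiml_loglik(small_params, Y) == pytest.approx(want, abs=1e-10)

    def test_family_with_one_wave_rejected(self, small_params):
        rng = np.random.default_rng(2)
        Y = _simulate_wide(small_params, 10, 3, rng)
        Y[0, 3:] = np.nan  # only wave 0 observed
        with pytest.raises(ValueError, match="fewer than 2"):
            fiml_loglik(small_params, Y)

    def test_analytic_gradient_matches_finite_differences(self, small_params):
        rng = np.random.default_rng(3)
        p, W = 3, 3
        Y = _simulate_wide(small_params, 30, W, rng, miss=0.2)
        mask = ~np.isnan(Y)
        Yz = np.where(mask, Y, 0.0)
        patterns = _group_patterns(mask)
        index = _param_index(EdgeConstraintSet.saturated(p), p)
        theta = _pack(small_params, index)
        names = small_params.node_names
        _, g = _loglik_grad_core(theta, index, p, W, Yz, patterns, names)
        h = 1e-6
        for k in range(0, len(theta), 5):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            lp, _ = _loglik_grad_core(tp, index, p, W, Yz, patterns, names,
                                      want_grad=False)
            lm, _ = _loglik_grad_core(tm, index, p, W, Yz, patterns, names,
                                      want_grad=False)
            assert g[k] == pytest.approx((lp - lm) / (2 * h), rel=1e-4, abs=1e-6)

    def test_likelihood_invariant_under_node_relabeling(self, small_params):
        rng = np.random.default_rng(4)
        W = 3
        Y = _simulate_wide(small_params, 20, W, rng)
        perm = [2, 0, 1]
        P = np.eye(3)[perm]
        permuted = PanelGVARParams(
            [small_params.node_names[i] for i in perm],
            small_params.mu[perm], P @ small_params.B @ P.T,
            P @ small_params.K_within @ P.T, P @ small_params.K_between @ P.T)
        Yp = Y.reshape(-1, W, 3)[:, :, perm].reshape(-1, W * 3)
        assert fiml_loglik(permuted, Yp) == pytest.approx(
            fiml_loglik(small_params, Y), abs=1e-8)


@pytest.fixture(scope="module")
def loop_truth():
    loop = [("m_overwhelmed", "c_worry", 0.15), ("c_worry", "c_nervous", 0.15),
            ("c_nervous", "m_overwhelmed", 0.15)]
    return make_gvar_truth(
        n_nodes_per_member={"child": ("c_worry", "c_nervous", "c_unhappy"),
                            "mother": ("m_overwhelmed", "m_strain", "m_unhappy")},
        cross_member_paths=loop, autoregression=0.3), loop


@pytest.fixture(scope="module")
def loop_panel(loop_truth):
    truth, _ = loop_truth
    spec = FamilyPanelSpec(n_families=1200, n_waves=4, seed=55)
    return simulate_panel(truth, spec)


@pytest.fixture(scope="module")
def saturated_fit(loop_truth, loop_panel):
    truth, _ = loop_truth
    return fit_panel_gvar(loop_panel, truth.node_names, name="saturated")


class TestFit:
    def test_recovers_temporal_matrix(self, loop_truth, saturated_fit):
        truth, _ = loop_truth
        rmse = np.sqrt(((saturated_fit.params.B - truth.B) ** 2).mean())
        assert rmse < 0.06
        assert saturated_fit.converged

    def test_refit_from_solution_is_fixed_point(self, loop_truth, loop_panel,
                                                saturated_fit):
        truth, _ = loop_truth
        again = fit_panel_gvar(loop_panel, truth.node_names,
                               start=saturated_fit.params, compute_se=False)
        assert again.loglik == pytest.approx(saturated_fit.loglik, abs=1e-6)

    def test_recovery_improves_with_sample_size(self, small_params):
        rng = np.random.default_rng(6)
        errs = {}
        for n in (300, 1500):
            Y = _simulate_wide(small_params, n, 4, rng)
            f = fit_panel_gvar(Y, small_params.node_names, compute_se=False)
            errs[n] = np.sqrt(((f.params.B - small_params.B) ** 2).mean())
        assert errs[1500] <= errs[300]


class TestPruneStepup:
    def test_pruned_model_keeps_only_significant_offdiagonals(
            self, loop_panel, loop_truth, saturated_fit):
        truth, _ = loop_truth
        _, pruned = prune(saturated_fit, loop_panel, alpha=0.05)
        offdiag = [k for k, (blk, i, j) in enumerate(pruned.param_index)
                   if blk in ("B", "Kw", "Kb") and i != j]
        assert pruned.converged
        assert all(pruned.wald_p[k] < 0.05 for k in offdiag)
        assert pruned.n_free_parameters < saturated_fit.n_free_parameters

    def test_stepup_never_worsens_bic(self, loop_panel, loop_truth,
                                      saturated_fit):
        truth, _ = loop_truth
        _, pruned = prune(saturated_fit, loop_panel, alpha=0.05)
        final = stepup(pruned, loop_panel, criterion="bic")
        assert final.bic <= pruned.bic + 1e-9

    def test_prune_requires_converged_fit(self, saturated_fit, loop_panel):
        from dataclasses import replace
        bad = replace(saturated_fit, converged=False)
        with pytest.raises(ValueError):
            prune(bad, loop_panel)


class TestFitIndices:
    def test_saturated_is_exact_fit(self, loop_truth, loop_panel,
                                    saturated_fit):
        truth, _ = loop_truth
        p = len(truth.node_names)
        baseline = fit_panel_gvar(loop_panel, truth.node_names,
                                  constraints=EdgeConstraintSet.independence(p),
                                  compute_se=False)
        fi = fit_indices(saturated_fit, saturated_fit, baseline)
        assert fi["rmsea"] == 0.0
        assert fi["cfi"] == 1.0
        assert fi["df"] == 0

    def test_lr_statistic_matches_direct_recomputation(
            self, loop_truth, loop_panel, saturated_fit):
        truth, _ = loop_truth
        p = len(truth.node_names)
        baseline = fit_panel_gvar(loop_panel, truth.node_names,
                                  constraints=EdgeConstraintSet.independence(p),
                                  compute_se=False)
        fi = fit_indices(baseline, saturated_fit, baseline)
        assert fi["T"] == pytest.approx(
            2 * (saturated_fit.loglik - baseline.loglik), abs=1e-8)
        assert fi["df"] == saturated_fit.n_free_parameters - baseline.n_free_parameters
        assert 0 <= fi["cfi"] <= 1


class TestPipeline:
    def test_report_contains_three_fits_and_is_deterministic(self, loop_truth):
        truth, loop = loop_truth
        spec = FamilyPanelSpec(n_families=600, n_waves=4, seed=77)
        panel = simulate_panel(truth, spec)
        r1 = model_selection_pipeline(panel, truth.node_names)
        r2 = model_selection_pipeline(panel, truth.node_names)
        assert {"saturated", "pruned", "final"} <= set(r1)
        assert len(r1["comparison"]) == 3
        assert r1["final"].loglik == r2["final"].loglik
        assert r1["comparison"].equals(r2["comparison"])

    def test_constraint_masks_validate(self):
        with pytest.raises(ValueError):
            EdgeConstraintSet(np.ones((2, 2), bool),
                              np.array([[True, True], [False, True]]),
                              np.ones((2, 2), bool))
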