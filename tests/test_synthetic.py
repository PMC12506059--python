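"""Generator correctness: PD/stationarity invariants, closed-form and
Monte-Carlo moments, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import solve_discrete_lyapunov

from famnet.synthetic_data import (
    FamilyPanelSpec, GGMTruth, discretize_likert, family_triad_truth,
    make_ggm_truth, make_gvar_truth, simulate_cross_sectional, simulate_panel,
)


class TestMakeGGMTruth:
    def test_positive_definite_across_seeds(self):
        for seed in range(10):
            t = make_ggm_truth(9, within_density=0.7, between_density=0.3,
                               seed=seed)
            assert np.linalg.eigvalsh(t.precision).min() > 0
            pc = t.partial_correlations
            assert np.all(np.abs(pc) < 1)

    def test_zero_between_density_gives_no_cross_edges(self):
        comm = {f"x{i}": ("a" if i < 3 else "b") for i in range(6)}
        t = make_ggm_truth(6, communities=comm, within_density=0.8,
                           between_density=0.0, seed=4)
        pc = t.partial_correlations
        labels = [comm[n] for n in t.node_names]
        for i in range(6):
            for j in range(6):
                if labels[i] != labels[j]:
                    assert pc[i, j] == 0

    def test_zero_density_gives_diagonal_precision(self):
        t = make_ggm_truth(5, within_density=0.0, between_density=0.0, seed=1)
        assert np.allclose(t.precision, np.eye(5))

    def test_rejects_degenerate_requests(self):
        with pytest.raises(ValueError):
            make_ggm_truth(1)
        with pytest.raises(ValueError):
            make_ggm_truth(4, weight_range=(0.0, 1.2))
        with pytest.raises(ValueError):
            make_ggm_truth(4, within_density=1.5)

    def test_triad_truth_layout(self):
        t = family_triad_truth()
        assert len(t.node_names) == 9
        assert sorted(set(t.communities.values())) == ["child", "father", "mother"]
        pc = t.partial_correlations
        idx = {n: i for i, n in enumerate(t.node_names)}
        # no independent father-child association by default
        for c in ("c_int", "c_ext", "c_pro"):
            for f in ("f_emo", "f_sd", "f_lc"):
                assert pc[idx[c], idx[f]] == 0
        assert pc[idx["m_emo"], idx["c_int"]] > 0


class TestSimulateCrossSectional:
    def test_identity_precision_gives_uncorrelated_columns(self):
        t = make_ggm_truth(4, within_density=0, between_density=0, seed=0)
        data = simulate_cross_sectional(t, 200_000, seed=5)
        corr = np.corrcoef(data.to_numpy(), rowvar=False)
        np.fill_diagonal(corr, 0)
        assert np.abs(corr).max() < 0.01

    def test_sample_covariance_converges_to_truth(self, triad_truth):
        data = simulate_cross_sectional(triad_truth, 200_000, seed=6)
        err = np.abs(np.cov(data.to_numpy(), rowvar=False) - triad_truth.covariance)
        assert err.max() < 0.02

    def test_likert_levels_and_determinism(self, triad_truth):
        a = simulate_cross_sectional(triad_truth, 500, likert_levels=3, seed=9)
        b = simulate_cross_sectional(triad_truth, 500, likert_levels=3, seed=9)
        assert set(np.unique(a.to_numpy())) <= {0.0, 1.0, 2.0}
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_bad_n(self, triad_truth):
        with pytest.raises(ValueError):
            simulate_cross_sectional(triad_truth, 0)


class TestDiscretizeLikert:
    def test_stated_examples(self):
        assert discretize_likert(np.array([0.0]), 3, (-0.43, 0.43))[0] == 1
        assert discretize_likert(np.array([-9.0]), 4)[0] == 0
        assert discretize_likert(np.array([9.0]), 4)[0] == 3

    def test_rejects_non_monotone_thresholds(self):
        with pytest.raises(ValueError):
            discretize_likert(np.zeros(3), 3, (0.5, -0.5))

    def test_quantile_thresholds_give_equal_mass(self):
        rng = np.random.default_rng(3)
        lv = discretize_likert(rng.standard_normal(100_000), 3)
        freqs = np.bincount(lv, minlength=3) / 100_000
        assert np.abs(freqs - 1 / 3).max() < 0.01


class TestMakeGVARTruth:
    def test_pure_autoregression(self):
        t = make_gvar_truth(n_nodes_per_member={"child": 2}, autoregression=0.3)
        assert np.allclose(t.B, 0.3 * np.eye(2))

    def test_loop_support_exact(self):
        loop = [("m_overwhelmed", "c_worry", 0.2), ("c_worry", "c_nervous", 0.2),
                ("c_nervous", "m_overwhelmed", 0.2)]
        t = make_gvar_truth(cross_member_paths=loop)
        off = t.B - np.diag(np.diag(t.B))
        assert (off != 0).sum() == 3
        idx = {n: i for i, n in enumerate(t.node_names)}
        for src, tgt, w in loop:
            assert t.B[idx[tgt], idx[src]] == pytest.approx(w)

    def test_spectral_radius_enforced(self):
        t = make_gvar_truth(n_nodes_per_member={"child": 2},
                            cross_member_paths=[("c_0", "c_1", 5.0)],
                            autoregression=0.5)
        assert t.spectral_radius <= 0.9 + 1e-12

    def test_unknown_node_rejected(self):
        with pytest.raises(ValueError):
            make_gvar_truth(cross_member_paths=[("nope", "c_worry", 0.1)])


class TestSimulatePanel:
    def test_iid_waves_when_no_dynamics(self):
        t = make_gvar_truth(n_nodes_per_member={"child": 1}, autoregression=0.0,
                            between_variance=0.0, contemporaneous_cor=0.0)
        spec = FamilyPanelSpec(n_families=20_000, n_waves=3, seed=2)
        wide = simulate_panel(t, spec, burn_in=5).to_wide().to_numpy()
        r01 = np.corrcoef(wide[:, 0], wide[:, 1])[0, 1]
        assert abs(r01) < 0.02

    def test_stationary_variance_closed_form(self):
        # B = 0.5 I, innovation var 1, no intercept: var = 1/(1-0.25)
        t = make_gvar_truth(n_nodes_per_member={"child": 2}, autoregression=0.5,
                            between_variance=0.0, contemporaneous_cor=0.0)
        spec = FamilyPanelSpec(n_families=30_000, n_waves=2, seed=3)
        wide = simulate_panel(t, spec, burn_in=60).to_wide().to_numpy()
        assert np.allclose(wide.var(axis=0), 4 / 3, atol=0.05)

    def test_lag_cross_covariance_matches_lyapunov(self):
        t = make_gvar_truth(
            n_nodes_per_member={"child": 2, "mother": 1},
            cross_member_paths=[("m_0", "c_0", 0.25)], autoregression=0.4,
            between_variance=0.0)
        spec = FamilyPanelSpec(n_families=20_000, n_waves=4, seed=4)
        wide = simulate_panel(t, spec, burn_in=60).to_wide().to_numpy()
        p = 3
        S0 = solve_discrete_lyapunov(t.B, t.sigma_zeta)
        X = wide.reshape(-1, 4, p)
        for h in (0, 1, 2):
            emp = np.zeros((p, p))
            cnt = 0
            for s in range(4 - h):
                a = X[:, s, :] - X[:, s, :].mean(0)
                b = X[:, s + h, :] - X[:, s + h, :].mean(0)
                emp += a.T @ b / len(a)
                cnt += 1
            emp /= cnt
            expected = S0 @ np.linalg.matrix_power(t.B.T, h)
            assert np.abs(emp - expected).max() < 0.02

    def test_complete_panel_and_flags(self):
        t = make_gvar_truth(n_nodes_per_member={"child": 2})
        spec = FamilyPanelSpec(n_families=50, n_waves=4, missing_wave_rate=0.0,
                               seed=5)
        panel = simulate_panel(t, spec)
        assert (panel.waves_per_family() == 4).all()
        assert panel.low_wave_families == []
        spec2 = FamilyPanelSpec(n_families=200, n_waves=3,
                                missing_wave_rate=0.6, seed=6)
        panel2 = simulate_panel(t, spec2)
        counts = panel2.waves_per_family()
        # flagged families are exactly those with <2 observed waves, and
        # none of them have been dropped from the data
        observed_low = set(panel2.low_wave_families)
        from_data = set(counts.index[counts < 2])
        assert from_data <= observed_low

    def test_determinism(self):
        t = make_gvar_truth(n_nodes_per_member={"child": 2})
        spec = FamilyPanelSpec(n_families=30, n_waves=3, missing_wave_rate=0.2,
                               seed=8)
        a = simulate_panel(t, spec).data
        b = simulate_panel(t, spec).data
        pd.testing.assert_frame_equal(a, b)
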