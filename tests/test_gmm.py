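"""Two-step GMM: moment vectors, weighting, optimization and inference."""

import numpy as np
import pytest
import statsmodels.api as sm

from partgmm import (
    MomentSet,
    PanelDataset,
    SyntheticSpec,
    build_partitioned_design,
    candidate_moments,
    fit_independence,
    fit_two_step,
    generate_panel,
    moment_jacobian,
    moment_vector,
    screen_columns,
    wald_table,
    weight_matrix,
)
from partgmm.gmm import lag_group_name
from partgmm.moments import ExtraMoment


def screened(data, **kwargs):
    design = build_partitioned_design(data, **kwargs)
    kept, dropped = screen_columns(design)
    return design.select_columns(kept), dropped


class TestIndependenceFit:
    def test_single_wave_matches_logistic_mle(self):
        spec = SyntheticSpec(n_subjects=600, n_waves=1, beta_lag=[[1.0], [-0.5]], seed=4)
        data = generate_panel(spec)
        design, _ = screened(data)
        beta, _ = fit_independence(data.y.reshape(-1), design.Z)
        ref = sm.Logit(data.y.reshape(-1), design.Z).fit(disp=0)
        np.testing.assert_allclose(beta, ref.params, atol=1e-6)

    def test_pooled_fit_matches_glm_on_panel(self, default_panel):
        design, _ = screened(default_panel)
        beta, _ = fit_independence(default_panel.y.reshape(-1), design.Z)
        ref = sm.GLM(default_panel.y.reshape(-1), design.Z, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(beta, ref.params, atol=1e-6)

    def test_all_zero_lag_column_dropped(self):
        # covariate absent (all zero) at wave 1 makes its lag-3 column all-zero
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, (300, 4)).astype(float)
        x[:, 0] = 0.0
        y = rng.integers(0, 2, (300, 4))
        data = PanelDataset(subject_ids=np.arange(300), y=y, x_td=x[:, :, None],
                            td_names=["c"], x_fixed=np.zeros((300, 0)), fixed_names=[])
        design, dropped = screened(data)
        assert ("c", 3) in dropped
        assert ("c", 3) not in design.column_labels


class TestMomentVector:
    def test_zero_at_independence_solution(self, default_panel):
        design, _ = screened(default_panel)
        beta, _ = fit_independence(default_panel.y.reshape(-1), design.Z)
        mset = MomentSet(baseline_labels=list(design.column_labels))
        _, gbar = moment_vector(beta, default_panel, design, mset)
        assert np.max(np.abs(gbar)) < 1e-8

    def test_single_subject_extra_component(self):
        data = PanelDataset(subject_ids=[1], y=np.array([[1.0, 1.0]]),
                            x_td=np.ones((1, 2, 1)), td_names=["x"],
                            x_fixed=np.zeros((1, 0)), fixed_names=[])
        design = build_partitioned_design(data, max_lag=0).select_columns([0, 1])
        mset = MomentSet(baseline_labels=list(design.column_labels),
                         extras=[ExtraMoment(0, "x", 2, 1)])
        beta = np.array([np.log(1.0 / 3.0), 0.0])  # mu = 0.25 everywhere
        g, _ = moment_vector(beta, data, design, mset)
        assert g[0, -1] == pytest.approx(1.0 * (1.0 - 0.25))

    def test_matches_naive_double_loop(self, rng, default_panel):
        data = default_panel
        design, _ = screened(data)
        cands = candidate_moments(data, design.max_lag)[:5]
        mset = MomentSet(baseline_labels=list(design.column_labels), extras=cands)
        beta = rng.normal(scale=0.3, size=design.p)
        g, gbar = moment_vector(beta, data, design, mset)

        from scipy.special import expit
        n, t, p = data.n_subjects, data.n_waves, design.p
        zr = design.Z.reshape(n, t, p)
        g_ref = np.zeros((n, mset.m))
        for i in range(n):
            mu_i = expit(zr[i] @ beta)
            for c in range(p):
                g_ref[i, c] = sum(zr[i, w, c] * (data.y[i, w] - mu_i[w]) for w in range(t))
            for k, e in enumerate(cands):
                mu_it = expit(zr[i, e.outcome_wave - 1] @ beta)
                g_ref[i, p + k] = data.x_td[i, e.cov_wave - 1, e.cov_index] * (
                    data.y[i, e.outcome_wave - 1] - mu_it
                )
        np.testing.assert_allclose(g, g_ref, atol=1e-12)
        np.testing.assert_allclose(gbar, g_ref.mean(axis=0), atol=1e-12)

    def test_jacobian_matches_finite_differences(self, rng, default_panel):
        data = default_panel
        design, _ = screened(data)
        cands = candidate_moments(data, design.max_lag)[:4]
        mset = MomentSet(baseline_labels=list(design.column_labels), extras=cands)
        beta = rng.normal(scale=0.2, size=design.p)
        big_g = moment_jacobian(beta, data, design, mset)
        h = 1e-6
        for c in range(design.p):
            bp, bm = beta.copy(), beta.copy()
            bp[c] += h
            bm[c] -= h
            _, gp = moment_vector(bp, data, design, mset)
            _, gm = moment_vector(bm, data, design, mset)
            np.testing.assert_allclose(big_g[:, c], (gp - gm) / (2 * h), atol=1e-6)


class TestWeightMatrix:
    def test_symmetric_pair_scalar(self):
        a = 0.7
        g = np.array([[a], [-a]])
        w = weight_matrix(g)
        assert w[0, 0] == pytest.approx(1.0 / a**2)

    def test_identity_second_moment(self, rng):
        # orthonormal-by-construction g columns: S = I -> W = I
        g = rng.standard_normal((4000, 3))
        s = g.T @ g / 4000
        l = np.linalg.cholesky(s)
        g = g @ np.linalg.inv(l).T
        np.testing.assert_allclose(weight_matrix(g), np.eye(3), atol=1e-8)

    def test_inverse_property(self, rng):
        g = rng.standard_normal((500, 6)) @ rng.standard_normal((6, 6))
        s = g.T @ g / 500
        np.testing.assert_allclose(weight_matrix(g) @ s, np.eye(6), atol=1e-8)

    def test_degenerate_component_regularized_not_failed(self, rng):
        g = np.hstack([rng.standard_normal((100, 2)), np.zeros((100, 1))])
        with pytest.warns(UserWarning):
            w = weight_matrix(g)
        assert np.all(np.isfinite(w))
        np.testing.assert_allclose(w, w.T)


class TestTwoStep:
    def test_just_identified_equals_independence(self, default_panel):
        design, dropped = screened(default_panel)
        beta1, _ = fit_independence(default_panel.y.reshape(-1), design.Z)
        mset = MomentSet(baseline_labels=list(design.column_labels))
        fit = fit_two_step(default_panel, design, mset, dropped_labels=dropped)
        np.testing.assert_allclose(fit.beta, beta1, atol=1e-6)
        assert fit.objective < 1e-8
        assert np.max(np.abs(fit.gbar)) < 1e-8
        assert fit.j_df == 0

    def test_overidentified_fit_reports_j(self, default_panel):
        design, dropped = screened(default_panel)
        cands = candidate_moments(default_panel, design.max_lag)
        mset = MomentSet(baseline_labels=list(design.column_labels), extras=cands)
        fit = fit_two_step(default_panel, design, mset, dropped_labels=dropped)
        assert fit.j_df == len(cands)
        assert fit.j_stat >= 0.0
        assert 0.0 <= fit.j_pvalue <= 1.0
        assert fit.converged

    def test_vcov_psd_and_ci_order(self, default_panel):
        design, _ = screened(default_panel)
        mset = MomentSet(baseline_labels=list(design.column_labels))
        fit = fit_two_step(default_panel, design, mset)
        evals = np.linalg.eigvalsh(fit.vcov)
        assert evals.min() > -1e-12
        ci = fit.conf_int
        assert np.all(ci[:, 0] <= fit.odds_ratios) and np.all(fit.odds_ratios <= ci[:, 1])
        assert np.all(fit.odds_ratios > 0)

    def test_continuous_covariate_scaling_invariance(self):
        rng = np.random.default_rng(3)
        n, t = 700, 3
        x = rng.normal(size=(n, t, 1))
        from scipy.special import expit
        y = (rng.random((n, t)) < expit(0.3 + 0.8 * x[:, :, 0])).astype(float)
        base = dict(td_names=["dose"], x_fixed=np.zeros((n, 0)), fixed_names=[])
        d1 = PanelDataset(subject_ids=np.arange(n), y=y, x_td=x, **base)
        d2 = PanelDataset(subject_ids=np.arange(n), y=y, x_td=2.5 * x, **base)
        fits = []
        for d in (d1, d2):
            design, _ = screened(d)
            mset = MomentSet(baseline_labels=list(design.column_labels))
            fits.append(fit_two_step(d, design, mset))
        td_idx = [i for i, (nm, lag) in enumerate(fits[0].column_labels) if lag is not None]
        np.testing.assert_allclose(
            fits[0].beta[td_idx], 2.5 * np.asarray(fits[1].beta)[td_idx], atol=1e-6
        )


class TestWaldTable:
    def test_or_from_log_coefficient(self):
        assert np.exp(1.4134) == pytest.approx(4.11, abs=5e-3)

    def test_null_coefficient_row(self, default_panel):
        design, _ = screened(default_panel)
        mset = MomentSet(baseline_labels=list(design.column_labels))
        fit = fit_two_step(default_panel, design, mset)
        fit.beta[2] = 0.0
        fit.se[2] = 0.1
        row = fit.params_frame().iloc[2]
        assert row["or"] == pytest.approx(1.0)
        assert row["ci_low"] == pytest.approx(0.822, abs=1e-3)
        assert row["ci_high"] == pytest.approx(1.2165, abs=1e-3)
        assert row["p_value"] == pytest.approx(1.0)

    def test_groups_ordered_by_lag(self, default_panel):
        design, _ = screened(default_panel)
        mset = MomentSet(baseline_labels=list(design.column_labels))
        fit = fit_two_step(default_panel, design, mset)
        table = wald_table(fit)
        groups = list(dict.fromkeys(table["group"]))
        assert groups == [
            "Cross sectional", "One time period lag",
            "Two time period lag", "Three time period lag",
        ]

    def test_group_names(self):
        assert lag_group_name(None) == "Cross sectional"
        assert lag_group_name(0) == "Cross sectional"
        assert lag_group_name(1) == "One time period lag"
        assert lag_group_name(5) == "5 time period lag"

    def test_dropped_coefficient_present_as_nan(self, default_panel):
        design, dropped = screened(default_panel)
        mset = MomentSet(baseline_labels=list(design.column_labels))
        fit = fit_two_step(default_panel, design, mset, dropped_labels=[("ghost", 3)])
        table = wald_table(fit)
        row = table[table["name"] == "ghost"].iloc[0]
        assert row["status"] == "dropped" and np.isnan(row["or"])
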