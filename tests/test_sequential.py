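"""Sequential-effect regressions: global OLS and local WLS beta maps."""

import numpy as np
import pandas as pd
import pytest

import relfreq as rf
from relfreq.core import logodds
from relfreq.sequential import _lagged_design, default_map_grid


class TestSequentialOLS:
    def test_identity_generator_with_shuffled_stimuli(self, rng):
        # shuffling breaks stimulus autocorrelation so the lag coefficient
        # cannot inherit signal from R_{n-1} = S_{n-1}
        p = rng.permutation(np.tile(rf.SUPPORT, 8))
        trials = pd.DataFrame(
            {"participant_id": 1, "trial_index": np.arange(1, p.size + 1), "p": p, "response": p}
        )
        res = rf.fit_sequential_ols(trials)
        assert res.beta0 == pytest.approx(1.0, abs=1e-9)
        assert res.beta_prev == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_lag_coefficient(self, uniform_pmf):
        params = rf.ObserverParams(
            model="LLO-L", beta0=0.8, beta_lags=(0.05,), betaC=0.0, sigma_noise=0.3
        )
        stim = rf.generate_stimulus_sequence(uniform_pmf, rf.ExperimentDesign(), seed=40)
        trials = rf.simulate_observer(params, stim, seed=41)
        res = rf.fit_sequential_ols(trials)
        assert res.beta_prev == pytest.approx(0.05, abs=0.02)

    def test_agrees_with_normal_equations_oracle(self, rng):
        p = rng.choice(rf.SUPPORT, size=50)
        resp = np.clip(p + rng.normal(0, 0.05, 50), 0.005, 0.995)
        trials = pd.DataFrame(
            {"participant_id": 1, "trial_index": np.arange(1, 51), "p": p, "response": resp}
        )
        res = rf.fit_sequential_ols(trials)
        y, X, _, _ = _lagged_design(trials, 1)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.beta0 == pytest.approx(beta[0], abs=1e-10)
        assert res.beta_prev == pytest.approx(beta[1], abs=1e-10)
        assert res.betaC == pytest.approx(beta[2], abs=1e-10)

    def test_white_noise_lag_coefficient_near_zero(self, rng):
        # responses unrelated to everything: beta_{-1} within 3 SEs of 0
        p = rng.choice(rf.SUPPORT, size=2000)
        resp = np.clip(rng.uniform(0.2, 0.8, 2000), 0.005, 0.995)
        trials = pd.DataFrame(
            {"participant_id": 1, "trial_index": np.arange(1, 2001), "p": p, "response": resp}
        )
        res = rf.fit_sequential_ols(trials)
        y, X, _, _ = _lagged_design(trials, 1)
        resid = y - X @ np.array([res.beta0, res.beta_prev, res.betaC])
        se = np.sqrt(
            (resid @ resid / (y.size - 3)) * np.linalg.inv(X.T @ X)[1, 1]
        )
        assert abs(res.beta_prev) < 3 * se

    def test_collinear_design_rejected(self):
        trials = pd.DataFrame(
            {
                "participant_id": 1,
                "trial_index": np.arange(1, 41),
                "p": np.full(40, 0.5),
                "response": np.full(40, 0.5),
            }
        )
        with pytest.raises(ValueError, match="collinear"):
            rf.fit_sequential_ols(trials)


class TestWLSBetaMap:
    def test_huge_kernel_span_equals_global_ols(self, alnl_participant):
        res = rf.fit_sequential_ols(alnl_participant)
        m = rf.wls_beta_map(alnl_participant, sigma_k=1e3, grid=default_map_grid(5))
        assert np.allclose(m.beta, res.beta_prev, atol=1e-6)

    def test_single_cell_matches_weighted_normal_equations(self, alnl_participant):
        sigma_k = 0.1
        center = 0.35
        m = rf.wls_beta_map(alnl_participant, sigma_k=sigma_k, grid=np.array([center]))
        y, X, pn, pprev = _lagged_design(alnl_participant, 1)
        w = (1 / (2 * np.pi * sigma_k**2)) * np.exp(
            -((pn - center) ** 2 + (pprev - center) ** 2) / (2 * sigma_k**2)
        )
        # explicit (X^T W X)^-1 X^T W Y with W = diag(w^2)
        W = np.diag(w**2)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        assert m.beta[0, 0] == pytest.approx(beta[1], abs=1e-10)

    def test_diagonal_ridge_for_nonlinear_generator(self, alnl_cohort):
        m = rf.wls_beta_map(alnl_cohort)
        d = np.abs(m.grid_pn[:, None] - m.grid_pprev[None, :])
        near = np.isfinite(m.beta) & (d <= 0.15)
        far = np.isfinite(m.beta) & (d >= 0.4)
        assert np.nanmean(m.beta[near]) > np.nanmean(m.beta[far])

    def test_mirror_symmetry_of_estimator(self, alnl_participant):
        m = rf.wls_beta_map(alnl_participant, grid=default_map_grid(9))
        mirrored = alnl_participant.copy()
        mirrored["p"] = 1 - mirrored["p"]
        mirrored["response"] = 1 - mirrored["response"]
        mm = rf.wls_beta_map(mirrored, grid=default_map_grid(9))
        assert np.allclose(mm.beta, m.beta[::-1, ::-1], atol=1e-9, equal_nan=True)


class TestPredictedMapAndCorrelation:
    def test_identical_maps_correlate_perfectly(self, alnl_cohort):
        m = rf.wls_beta_map(alnl_cohort, grid=default_map_grid(7))
        assert rf.map_correlation(m, m) == pytest.approx(1.0, abs=1e-12)
        from dataclasses import replace

        neg = replace(m, beta=-m.beta)
        assert rf.map_correlation(m, neg) == pytest.approx(-1.0, abs=1e-12)

    def test_mismatched_grids_rejected(self, alnl_cohort):
        a = rf.wls_beta_map(alnl_cohort, grid=default_map_grid(5))
        b = rf.wls_beta_map(alnl_cohort, grid=default_map_grid(7))
        with pytest.raises(ValueError):
            rf.map_correlation(a, b)

    def test_linear_generator_predicts_flat_map(self, alnl_participant):
        params = rf.ObserverParams(
            model="LLO-L", beta0=0.8, beta_lags=(0.05,), betaC=0.0, sigma_noise=0.3
        )
        pred = rf.predicted_beta_map(
            params, alnl_participant, n_sim=8, seed=50, grid=default_map_grid(7)
        )
        # cell-to-cell spread shrinks toward Monte-Carlo noise for linear models
        assert np.nanstd(pred.beta) < 0.05
        assert np.nanmean(pred.beta) == pytest.approx(0.05, abs=0.03)

    def test_ridge_width_scales_with_omega(self, uniform_pmf):
        design = rf.ExperimentDesign(n_participants=4)

        def ridge_profile(omega):
            params = rf.ObserverParams(
                model="LLO-NL", beta0=0.8, beta_lags=(0.12,), betaC=0.0,
                omega=omega, sigma_noise=0.2,
            )
            coh = rf.simulate_cohort(design, "U", params, uniform_pmf, seed=51)
            m = rf.wls_beta_map(coh, grid=default_map_grid(13))
            d = np.abs(m.grid_pn[:, None] - m.grid_pprev[None, :])
            near = np.nanmean(m.beta[np.isfinite(m.beta) & (d <= 0.1)])
            mid = np.nanmean(m.beta[np.isfinite(m.beta) & (d > 0.3) & (d <= 0.6)])
            return near, mid

        near_narrow, mid_narrow = ridge_profile(0.5)
        near_wide, mid_wide = ridge_profile(4.0)
        # a wider scope-of-influence retains a larger *fraction* of the
        # diagonal effect away from the diagonal
        assert mid_wide / near_wide > mid_narrow / near_narrow + 0.2
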