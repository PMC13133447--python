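"""Lagged designs, Tikhonov fits, cross-validation, and model comparison."""

import numpy as np
import pytest

from semtrf.preprocess import EpochedData
from semtrf.trf import (
    LAMBDA_GRID,
    LagSpec,
    added_value,
    build_lagged_design,
    condition_trf,
    cross_validate_lambda,
    fit_tikhonov,
    regularization_matrix,
    score_prediction,
    valid_rows,
)

RATE = 100.0


def make_epochs(eeg, regs, names=None, rate=RATE):
    n_tr = eeg.shape[0]
    names = names or [f"f{i}" for i in range(regs.shape[2])]
    return EpochedData(
        eeg=eeg,
        regs=regs,
        feature_names=names,
        ch_names=[f"ch{i}" for i in range(eeg.shape[1])],
        rate=rate,
        labels=["c"] * n_tr,
    )


def white_noise_epochs(rng, n_tr=4, n_ch=2, n=600, kernel=None, lags=None, noise=0.0):
    """Epochs whose EEG is a known kernel convolved with white regressors."""
    regs = rng.standard_normal((n_tr, n, 1))
    eeg = np.zeros((n_tr, n_ch, n))
    for i in range(n_tr):
        D = build_lagged_design(regs[i], lags, intercept=False)
        sig = D @ kernel
        for c in range(n_ch):
            eeg[i, c] = (1 - 0.5 * c) * sig + noise * rng.standard_normal(n)
    return make_epochs(eeg, regs)


@pytest.fixture
def lag100():
    return LagSpec(-100.0, 400.0, RATE)


@pytest.fixture
def true_kernel(lag100):
    t = lag100.times_ms
    return np.exp(-0.5 * ((t - 150) / 50) ** 2) - 0.6 * np.exp(-0.5 * ((t - 60) / 30) ** 2)


class TestLagSpec:
    def test_lag_count_formula(self):
        spec = LagSpec(-100.0, 1000.0, 250.0)
        assert spec.n_lags == round((1000 - (-100)) / 1000 * 250) + 1 == 276

    def test_window_must_straddle_zero(self):
        with pytest.raises(ValueError):
            LagSpec(100.0, 400.0, 250.0)


class TestLaggedDesign:
    def test_positive_lag_shifts_forward(self):
        lags = LagSpec(-10.0, 10.0, 100.0)  # lags -1, 0, +1 samples
        D = build_lagged_design(np.array([1.0, 2.0, 3.0]), lags, intercept=False)
        np.testing.assert_array_equal(D[:, 0], [2.0, 3.0, 0.0])  # lag -1
        np.testing.assert_array_equal(D[:, 1], [1.0, 2.0, 3.0])  # lag 0
        np.testing.assert_array_equal(D[:, 2], [0.0, 1.0, 2.0])  # lag +1

    def test_intercept_column_last(self):
        lags = LagSpec(-10.0, 10.0, 100.0)
        D = build_lagged_design(np.ones(5), lags, intercept=True)
        np.testing.assert_array_equal(D[:, -1], np.ones(5))

    def test_window_longer_than_data_rejected(self):
        with pytest.raises(ValueError):
            build_lagged_design(np.ones(3), LagSpec(-100.0, 1000.0, 250.0))

    def test_unit_impulse_identifies_eeg_segment(self, rng):
        """Regressing EEG on a unit impulse returns the EEG as the kernel."""
        lags = LagSpec(-40.0, 200.0, RATE)
        n = 200
        x = np.zeros(n)
        x[60] = 1.0
        eeg = rng.standard_normal(n)
        D = build_lagged_design(x, lags, intercept=False)
        m = fit_tikhonov(D, eeg[:, None], 0.0, lags, ["f"], ["ch"], intercept=False)
        lag_idx = lags.samples
        expected = eeg[60 + lag_idx]
        np.testing.assert_allclose(m.weights[0, :, 0], expected, atol=1e-8)


class TestFitTikhonov:
    def test_ols_limit_square_design(self, rng):
        D = rng.standard_normal((6, 6))
        y = rng.standard_normal(6)
        lags = LagSpec(-10.0, 40.0, RATE)  # 6 lags, 1 feature
        m = fit_tikhonov(D, y[:, None], 0.0, lags, ["f"], ["ch"], intercept=False)
        np.testing.assert_allclose(
            m.weights.ravel(), np.linalg.solve(D, y), atol=1e-8
        )

    def test_oracle_normal_equations(self, rng, lag100, true_kernel):
        """lambda=0 matches brute-force normal equations on small instances."""
        n = 50
        x = rng.standard_normal(n)
        lags = LagSpec(-20.0, 60.0, RATE)
        D = build_lagged_design(x, lags, intercept=True)
        Y = rng.standard_normal((n, 3))
        m = fit_tikhonov(D, Y, 0.0, lags, ["f"], list("abc"))
        brute = np.linalg.pinv(D.T @ D) @ D.T @ Y
        est = np.concatenate([m.weights.reshape(-1, 3), m.intercept[None, :]])
        assert np.max(np.abs(est - brute)) < 1e-8

    def test_shrinkage_monotone(self, rng, lag100, true_kernel):
        ep = white_noise_epochs(rng, n_tr=1, lags=lag100, kernel=true_kernel, noise=0.2)
        D = build_lagged_design(ep.regs[0], lag100, intercept=True)
        norms = []
        for lam in [0.0, 1.0, 10.0, 100.0, 1000.0, 1e5]:
            m = fit_tikhonov(D, ep.eeg[0].T, lam, lag100, ["f"], ["a", "b"])
            norms.append(np.linalg.norm(m.weights))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_noiseless_kernel_recovery(self, rng, lag100, true_kernel):
        ep = white_noise_epochs(rng, n_tr=1, n=2000, lags=lag100, kernel=true_kernel)
        D = build_lagged_design(ep.regs[0], lag100, intercept=True)
        m = fit_tikhonov(D, ep.eeg[0].T, 0.0, lag100, ["f"], ["a", "b"])
        rms = np.sqrt(np.mean((m.weights[0, :, 0] - true_kernel) ** 2))
        assert rms < 1e-6

    def test_nonfinite_rejected(self, lag100):
        D = np.full((10, 3), np.nan)
        with pytest.raises(ValueError):
            fit_tikhonov(D, np.ones((10, 1)), 1.0, lag100, ["f"], ["ch"])

    def test_smooth_penalty_matrix_structure(self):
        M = regularization_matrix(1, 4, kind="smooth", intercept=False)
        expected = np.array(
            [[1, -1, 0, 0], [-1, 2, -1, 0], [0, -1, 2, -1], [0, 0, -1, 1]], dtype=float
        )
        np.testing.assert_array_equal(M, expected)


class TestCrossValidation:
    def test_noiseless_prefers_small_lambda(self, rng, lag100, true_kernel):
        ep = white_noise_epochs(rng, n_tr=4, lags=lag100, kernel=true_kernel)
        cv = cross_validate_lambda(ep, lag100, LAMBDA_GRID)
        assert cv.best_r > 0.99
        assert cv.best_lambda <= LAMBDA_GRID[6]

    def test_pure_noise_accuracy_near_zero(self, rng, lag100):
        eeg = rng.standard_normal((4, 2, 600))
        regs = rng.standard_normal((4, 600, 1))
        cv = cross_validate_lambda(make_epochs(eeg, regs), lag100)
        assert np.all(np.abs(cv.mean_r) < 0.15)

    def test_single_value_grid(self, rng, lag100, true_kernel):
        ep = white_noise_epochs(rng, n_tr=3, lags=lag100, kernel=true_kernel, noise=0.5)
        cv = cross_validate_lambda(ep, lag100, np.array([8.0]))
        assert cv.best_lambda == 8.0

    def test_single_trial_rejected(self, rng, lag100, true_kernel):
        ep = white_noise_epochs(rng, n_tr=1, lags=lag100, kernel=true_kernel)
        with pytest.raises(ValueError):
            cross_validate_lambda(ep, lag100)

    def test_matches_heldout_refit_oracle(self, rng, lag100, true_kernel):
        """Fold accuracy equals an explicit fit-on-train, score-on-test loop."""
        ep = white_noise_epochs(rng, n_tr=3, lags=lag100, kernel=true_kernel, noise=1.0)
        lam = 4.0
        cv = cross_validate_lambda(ep, lag100, np.array([lam]))
        valid = valid_rows(lag100, ep.eeg.shape[2])
        for hold in range(3):
            train = [i for i in range(3) if i != hold]
            D_tr = np.vstack(
                [build_lagged_design(ep.regs[i], lag100, True)[valid] for i in train]
            )
            Y_tr = np.vstack([ep.eeg[i].T[valid] for i in train])
            m = fit_tikhonov(D_tr, Y_tr, lam, lag100, ["f"], ep.ch_names)
            D_ho = build_lagged_design(ep.regs[hold], lag100, True)[valid]
            pred = D_ho[:, :-1] @ m.weights.reshape(-1, 2) + m.intercept
            obs = ep.eeg[hold].T[valid]
            r = [
                np.corrcoef(pred[:, c], obs[:, c])[0, 1] for c in range(2)
            ]
            assert cv.fold_r[0, hold] == pytest.approx(np.mean(r), abs=1e-10)


class TestScoring:
    def test_refit_trial_noiseless_r_one(self, rng, lag100, true_kernel):
        ep = white_noise_epochs(rng, n_tr=1, lags=lag100, kernel=true_kernel)
        D = build_lagged_design(ep.regs[0], lag100, intercept=True)
        m = fit_tikhonov(D, ep.eeg[0].T, 0.0, lag100, ["f"], ["a", "b"])
        r, mean_r = score_prediction(m, ep.regs[0], ep.eeg[0])
        assert np.all(r > 0.999) and mean_r > 0.999

    def test_orthogonal_signals_r_near_zero(self, rng, lag100, true_kernel):
        ep = white_noise_epochs(rng, n_tr=1, lags=lag100, kernel=true_kernel)
        D = build_lagged_design(ep.regs[0], lag100, intercept=True)
        m = fit_tikhonov(D, ep.eeg[0].T, 1.0, lag100, ["f"], ["a", "b"])
        other = rng.standard_normal(ep.eeg[0].shape)
        _, mean_r = score_prediction(m, ep.regs[0], other)
        assert abs(mean_r) < 0.1

    def test_three_sample_hand_correlation(self, lag100):
        """r for a 3-sample prediction reproduced against direct arithmetic."""
        pred = np.array([1.0, 2.0, 4.0])
        obs = np.array([1.0, 3.0, 2.0])
        expected = (
            ((pred - pred.mean()) * (obs - obs.mean())).sum()
            / np.sqrt(((pred - pred.mean()) ** 2).sum() * ((obs - obs.mean()) ** 2).sum())
        )
        from semtrf.trf import _pearson_columns

        got = _pearson_columns(pred[:, None], obs[:, None])[0]
        assert got == pytest.approx(expected, abs=1e-12)


class TestConditionTRF:
    def test_identical_epochs_equal_single_fit(self, rng, lag100, true_kernel):
        one = white_noise_epochs(rng, n_tr=1, lags=lag100, kernel=true_kernel, noise=0.3)
        two = make_epochs(
            np.repeat(one.eeg, 2, axis=0), np.repeat(one.regs, 2, axis=0)
        )
        m1 = condition_trf(one, 2.0, lag100)
        m2 = condition_trf(two, 2.0, lag100)
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-10)

    def test_baseline_window_zero_mean(self, rng, lag100, true_kernel):
        ep = white_noise_epochs(rng, n_tr=2, lags=lag100, kernel=true_kernel, noise=0.3)
        m = condition_trf(ep, 2.0, lag100)
        t = m.times_ms
        mask = (t >= -100) & (t <= -4)
        base = m.weights[:, mask, :].mean(axis=1)
        assert np.max(np.abs(base)) < 1e-9
        assert m.baseline_corrected

    def test_opposite_kernels_average_to_zero(self, rng, lag100, true_kernel):
        epA = white_noise_epochs(rng, n_tr=1, lags=lag100, kernel=true_kernel)
        epB = white_noise_epochs(rng, n_tr=1, lags=lag100, kernel=-true_kernel)
        epB = make_epochs(epB.eeg, epA.regs)  # same stimulus, inverted response
        both = make_epochs(
            np.concatenate([epA.eeg, -epA.eeg]), np.concatenate([epA.regs, epA.regs])
        )
        m = condition_trf(both, 0.1, lag100)
        assert np.max(np.abs(m.weights)) < 1e-8


class TestAddedValue:
    def test_zero_surprisal_channel_no_gain(self, rng, lag100):
        """An all-zero surprisal channel cannot change CV accuracy."""
        n_tr, n = 4, 600
        kernel = np.exp(-0.5 * ((lag100.times_ms - 150) / 50) ** 2)
        regs = np.zeros((n_tr, n, 3))
        eeg = np.zeros((n_tr, 2, n))
        for i in range(n_tr):
            regs[i, :, 0] = rng.standard_normal(n)
            regs[i, :, 1] = rng.standard_normal(n)
            D = build_lagged_design(regs[i, :, :1], lag100, intercept=False)
            eeg[i, 0] = D @ kernel + 0.3 * rng.standard_normal(n)
            eeg[i, 1] = -D @ kernel + 0.3 * rng.standard_normal(n)
        ep = make_epochs(eeg, regs, names=["envelope", "word_onset", "word_surprisal"])
        res = added_value(ep, lag100, np.array([1.0, 64.0]))
        assert res["delta_r"] == pytest.approx(0.0, abs=1e-9)
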