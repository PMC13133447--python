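"""Temporal response function estimation by Tikhonov-regularized regression.

A TRF is a linear kernel ``w(f, tau)`` mapping stimulus features to each EEG
channel across a window of time lags (default -100..1000 ms):

    y_c(t) = sum_f sum_tau w(f, tau, c) * x_f(t - tau) + b_c + noise.

Estimation solves the penalized normal equations ``(D'D + lambda*M) w = D'y``
on a lagged design matrix ``D``.  The penalty ``M`` is the identity
(classical ridge, default) or a per-feature second-difference smoothing
matrix; the intercept column is never penalized.  The regularization
strength is chosen by leave-one-trial-out cross-validation over a log-spaced
grid (2^-5 .. 2^15), scoring each held-out trial by the channel-averaged
Pearson correlation between predicted and observed EEG.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .preprocess import EpochedData

__all__ = [
    "LagSpec",
    "TRFModel",
    "CVResult",
    "LAMBDA_GRID",
    "build_lagged_design",
    "regularization_matrix",
    "fit_tikhonov",
    "cross_validate_lambda",
    "score_prediction",
    "condition_trf",
    "added_value",
]

logger = logging.getLogger(__name__)

#: Default exhaustive search grid: powers of two from 2^-5 to 2^15 (21 values).
LAMBDA_GRID = 2.0 ** np.arange(-5, 16)

ACOUSTIC_FEATURES = ["envelope", "word_onset"]
FULL_FEATURES = ["envelope", "word_onset", "word_surprisal"]


@dataclass(frozen=True)
class LagSpec:
    """Lag window in milliseconds plus the sampling rate it is realized at."""

    t_min_ms: float = -100.0
    t_max_ms: float = 1000.0
    rate: float = 250.0

    def __post_init__(self) -> None:
        if not self.t_min_ms < 0 < self.t_max_ms:
            raise ValueError("lag window must straddle zero (t_min < 0 < t_max)")

    @property
    def samples(self) -> np.ndarray:
        """Integer sample lags, causal lags positive."""
        lo = int(round(self.t_min_ms * self.rate / 1000.0))
        hi = int(round(self.t_max_ms * self.rate / 1000.0))
        return np.arange(lo, hi + 1)

    @property
    def times_ms(self) -> np.ndarray:
        return self.samples * 1000.0 / self.rate

    @property
    def n_lags(self) -> int:
        return len(self.samples)


def build_lagged_design(
    X: np.ndarray, lags: LagSpec, intercept: bool = True
) -> np.ndarray:
    """Time-lagged design matrix, feature-major column order.

    ``X`` is (samples x features).  Column ``(f, tau)`` holds feature ``f``
    delayed by ``tau`` samples (``col[t] = X[t - tau, f]``), zero-padded
    where the shift runs off the ends.  When ``intercept`` is true a constant
    column is appended last.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, n_feat = X.shape
    lag_samples = lags.samples
    if len(lag_samples) > n:
        raise ValueError("lag window longer than the data segment")
    n_lag = len(lag_samples)
    D = np.zeros((n, n_feat * n_lag + (1 if intercept else 0)))
    for f in range(n_feat):
        for j, tau in enumerate(lag_samples):
            col = f * n_lag + j
            if tau >= 0:
                D[tau:, col] = X[: n - tau, f]
            else:
                D[: n + tau, col] = X[-tau:, f]
    if intercept:
        D[:, -1] = 1.0
    return D


def valid_rows(lags: LagSpec, n_samples: int) -> slice:
    """Rows of a lagged design whose whole lag window lies inside the segment.

    Epochs cut from a continuous recording carry responses to stimuli from
    before the cut; restricting the fit to interior rows removes that
    truncated-history bias (the zero-padded edge rows are used for
    prediction but not for estimation).
    """
    lag_samples = lags.samples
    start = max(int(lag_samples[-1]), 0)
    stop = n_samples - max(-int(lag_samples[0]), 0)
    if stop - start < 2:
        raise ValueError("segment too short for the lag window")
    return slice(start, stop)


def regularization_matrix(
    n_features: int, n_lags: int, kind: str = "ridge", intercept: bool = True
) -> np.ndarray:
    """Penalty matrix M: identity ridge or per-feature second-difference.

    The smoothing variant penalizes curvature of the kernel along the lag
    axis within each feature block (tridiagonal 2/-1 with unit corners); it
    mirrors the classic "Tikhonov" option of lagged-regression toolboxes.
    The intercept (last row/column) is unpenalized in both variants.
    """
    p = n_features * n_lags + (1 if intercept else 0)
    if kind == "ridge":
        M = np.eye(p)
    elif kind == "smooth":
        M = np.zeros((p, p))
        for f in range(n_features):
            s = f * n_lags
            block = 2.0 * np.eye(n_lags)
            block[0, 0] = block[-1, -1] = 1.0
            block -= np.diag(np.ones(n_lags - 1), 1)
            block -= np.diag(np.ones(n_lags - 1), -1)
            M[s : s + n_lags, s : s + n_lags] = block
    else:
        raise ValueError(f"unknown penalty kind {kind!r}")
    if intercept:
        M[-1, :] = 0.0
        M[:, -1] = 0.0
    return M


def _solve_penalized(
    D: np.ndarray, Y: np.ndarray, lam: float, M: np.ndarray
) -> np.ndarray:
    if not (np.all(np.isfinite(D)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite values in design or response")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    A = D.T @ D + lam * M
    b = D.T @ Y
    try:
        return sla.solve(A, b, assume_a="sym")
    except sla.LinAlgError:
        return np.linalg.lstsq(A, b, rcond=None)[0]


@dataclass
class TRFModel:
    """Estimated TRF kernel: weights (features x lags x channels) plus lambda."""

    weights: np.ndarray
    lags: LagSpec
    lam: float
    feature_names: list[str]
    ch_names: list[str]
    intercept: np.ndarray
    baseline_corrected: bool = False

    @property
    def times_ms(self) -> np.ndarray:
        return self.lags.times_ms

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted EEG (samples x channels) for regressors X (samples x features)."""
        D = build_lagged_design(X, self.lags, intercept=False)
        F, L, C = self.weights.shape
        return D @ self.weights.reshape(F * L, C) + self.intercept

    def baseline_correct(self, window_ms: tuple[float, float] = (-100.0, -4.0)) -> "TRFModel":
        """Subtract the pre-zero baseline mean per feature and channel."""
        t = self.times_ms
        mask = (t >= window_ms[0]) & (t <= window_ms[1])
        if not mask.any():
            raise ValueError(f"no lags inside baseline window {window_ms}")
        w = self.weights - self.weights[:, mask, :].mean(axis=1, keepdims=True)
        return TRFModel(
            weights=w,
            lags=self.lags,
            lam=self.lam,
            feature_names=list(self.feature_names),
            ch_names=list(self.ch_names),
            intercept=self.intercept.copy(),
            baseline_corrected=True,
        )


def fit_tikhonov(
    design: np.ndarray,
    eeg: np.ndarray,
    lam: float,
    lags: LagSpec,
    feature_names: list[str],
    ch_names: list[str],
    penalty: str = "ridge",
    intercept: bool = True,
) -> TRFModel:
    """Solve ``(D'D + lam*M) w = D'y`` per channel on a prebuilt design.

    ``eeg`` is (samples x channels) aligned row-for-row with ``design``.
    At ``lam=0`` with a full-rank design this is the exact least-squares
    solution; as ``lam`` grows the kernel shrinks monotonically.
    """
    Y = np.atleast_2d(np.asarray(eeg, dtype=float))
    if Y.shape[0] != design.shape[0]:
        Y = Y.T
    if Y.shape[0] != design.shape[0]:
        raise ValueError("design rows and EEG samples differ")
    F, L = len(feature_names), lags.n_lags
    M = regularization_matrix(F, L, kind=penalty, intercept=intercept)
    W = _solve_penalized(design, Y, lam, M)
    if intercept:
        b = W[-1]
        W = W[:-1]
    else:
        b = np.zeros(Y.shape[1])
    return TRFModel(
        weights=W.reshape(F, L, -1),
        lags=lags,
        lam=lam,
        feature_names=list(feature_names),
        ch_names=list(ch_names),
        intercept=b,
    )


def _pearson_columns(pred: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r; zero-variance prediction columns score 0."""
    p = pred - pred.mean(axis=0)
    o = obs - obs.mean(axis=0)
    sp = np.sqrt((p**2).sum(axis=0))
    so = np.sqrt((o**2).sum(axis=0))
    r = np.zeros(pred.shape[1])
    ok = (sp > 0) & (so > 0)
    if not ok.all():
        warnings.warn("zero-variance prediction or response; r set to 0")
    r[ok] = (p[:, ok] * o[:, ok]).sum(axis=0) / (sp[ok] * so[ok])
    return r


def score_prediction(
    model: TRFModel, regs: np.ndarray, eeg: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-channel Pearson r between model prediction and observed EEG."""
    Y = np.asarray(eeg, dtype=float)
    if Y.shape[0] == len(model.ch_names) and Y.shape[0] != regs.shape[0]:
        Y = Y.T
    pred = model.predict(regs)
    r = _pearson_columns(pred, Y)
    return r, float(r.mean())


@dataclass
class CVResult:
    """Leave-one-trial-out accuracy profile over the lambda grid."""

    lambdas: np.ndarray
    mean_r: np.ndarray  # per lambda, averaged over folds and channels
    fold_r: np.ndarray  # (n_lambda, n_folds)
    best_lambda: float = field(init=False)

    def __post_init__(self) -> None:
        # smallest lambda attaining the maximum (argmax takes the first)
        self.best_lambda = float(self.lambdas[int(np.argmax(self.mean_r))])

    @property
    def best_r(self) -> float:
        return float(self.mean_r.max())


def _trial_designs(
    epochs: EpochedData, lags: LagSpec, features: list[str]
) -> list[np.ndarray]:
    f_idx = [epochs.feature_names.index(f) for f in features]
    return [
        build_lagged_design(epochs.regs[i][:, f_idx], lags, intercept=False)
        for i in range(epochs.n_trials)
    ]


def cross_validate_lambda(
    epochs: EpochedData,
    lags: LagSpec,
    lambdas: np.ndarray | None = None,
    features: list[str] | None = None,
) -> CVResult:
    """Leave-one-trial-out ridge CV with an exact unpenalized intercept.

    For every fold the model is fit on all remaining trials and scored on the
    held-out trial by channel-averaged Pearson r.  The unpenalized intercept
    is absorbed by centering the training sufficient statistics, which lets a
    single eigendecomposition per fold serve the whole lambda grid.  Ties on
    the grid resolve to the smallest lambda.
    """
    lambdas = LAMBDA_GRID if lambdas is None else np.asarray(lambdas, dtype=float)
    lambdas = np.sort(lambdas)
    features = features or list(epochs.feature_names)
    n_trials = epochs.n_trials
    if n_trials < 2:
        raise ValueError("cross-validation requires at least 2 trials")
    valid = valid_rows(lags, epochs.eeg.shape[2])
    designs = [D[valid] for D in _trial_designs(epochs, lags, features)]
    Ys = [epochs.eeg[i].T[valid] for i in range(n_trials)]  # samples x channels
    grams = [D.T @ D for D in designs]
    cross = [D.T @ Y for D, Y in zip(designs, Ys)]
    xsums = [D.sum(axis=0) for D in designs]
    ysums = [Y.sum(axis=0) for Y in Ys]
    ns = [D.shape[0] for D in designs]
    G, C = sum(grams), sum(cross)
    xs, ys, ntot = sum(xsums), sum(ysums), sum(ns)

    fold_r = np.zeros((len(lambdas), n_trials))
    for i in range(n_trials):
        nt = ntot - ns[i]
        xm = (xs - xsums[i]) / nt
        ym = (ys - ysums[i]) / nt
        Gc = (G - grams[i]) - nt * np.outer(xm, xm)
        Cc = (C - cross[i]) - nt * np.outer(xm, ym)
        evals, V = np.linalg.eigh(Gc)
        evals = np.clip(evals, 0.0, None)
        B = V.T @ Cc
        Dc = designs[i] - xm  # held-out design, centered by training means
        Yo = Ys[i]
        for j, lam in enumerate(lambdas):
            W = V @ (B / (evals + lam)[:, None])
            pred = Dc @ W + ym
            fold_r[j, i] = _pearson_columns(pred, Yo).mean()
    mean_r = fold_r.mean(axis=1)
    return CVResult(lambdas=lambdas, mean_r=mean_r, fold_r=fold_r)


def condition_trf(
    epochs: EpochedData,
    lam: float,
    lags: LagSpec,
    features: list[str] | None = None,
    penalty: str = "ridge",
    baseline_window_ms: tuple[float, float] = (-100.0, -4.0),
) -> TRFModel:
    """Per-epoch fit at a fixed lambda, averaged, then baseline-corrected.

    Epoch kernels are averaged (rather than refit on concatenated data) and
    the mean over the pre-onset baseline window is removed from every
    feature/channel kernel.
    """
    features = features or list(epochs.feature_names)
    f_idx = [epochs.feature_names.index(f) for f in features]
    valid = valid_rows(lags, epochs.eeg.shape[2])
    models = []
    for i in range(epochs.n_trials):
        D = build_lagged_design(epochs.regs[i][:, f_idx], lags, intercept=True)
        models.append(
            fit_tikhonov(
                D[valid],
                epochs.eeg[i].T[valid],
                lam,
                lags,
                features,
                epochs.ch_names,
                penalty=penalty,
            )
        )
    weights = np.mean([m.weights for m in models], axis=0)
    intercept = np.mean([m.intercept for m in models], axis=0)
    model = TRFModel(
        weights=weights,
        lags=lags,
        lam=lam,
        feature_names=features,
        ch_names=list(epochs.ch_names),
        intercept=intercept,
    )
    return model.baseline_correct(baseline_window_ms)


def added_value(
    epochs_by_condition: dict[str, EpochedData] | EpochedData,
    lags: LagSpec,
    lambdas: np.ndarray | None = None,
) -> dict:
    """Added predictive value of word surprisal for one participant.

    Compares the cross-validated accuracy of the *full* model (envelope,
    word onset, word surprisal) against the *acoustic* model (envelope, word
    onset), each at its own best lambda, averaged across conditions.
    Returns per-model accuracies and their difference ``delta_r``.
    """
    if isinstance(epochs_by_condition, EpochedData):
        epochs_by_condition = {"all": epochs_by_condition}
    acc_full, acc_acoustic = [], []
    for epochs in epochs_by_condition.values():
        cv_full = cross_validate_lambda(epochs, lags, lambdas, FULL_FEATURES)
        cv_ac = cross_validate_lambda(epochs, lags, lambdas, ACOUSTIC_FEATURES)
        acc_full.append(cv_full.best_r)
        acc_acoustic.append(cv_ac.best_r)
    r_full = float(np.mean(acc_full))
    r_acoustic = float(np.mean(acc_acoustic))
    return {
        "r_full": r_full,
        "r_acoustic": r_acoustic,
        "delta_r": r_full - r_acoustic,
    }


def cohort_added_value(
    cohort_epochs: list[dict[str, EpochedData] | EpochedData],
    lags: LagSpec,
    lambdas: np.ndarray | None = None,
) -> dict:
    """Group-level surprisal added value: per-subject delta_r plus the test.

    Runs :func:`added_value` per participant and tests the cohort's delta_r
    with a one-sided Wilcoxon signed-rank test (H1: median > 0); the effect
    size is mean/SD of delta_r.  A warning note is attached below 5
    participants.
    """
    from .stats import wilcoxon_signed_rank

    per_subject = [added_value(ep, lags, lambdas) for ep in cohort_epochs]
    delta = np.array([r["delta_r"] for r in per_subject])
    test = wilcoxon_signed_rank(delta, alternative="greater")
    return {
        "delta_r": delta,
        "per_subject": per_subject,
        "wilcoxon": test,
        "cohens_d": float(delta.mean() / delta.std(ddof=1)),
    }
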