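"""Multivariate temporal response function (TRF) estimation.

The continuous EEG response is modelled as a sum of convolutions of binary
stimulus impulse trains with per-feature kernels,

    R_ch(t) = sum_i (w_i  *  S_i)(t) + eps_ch(t),

with kernel weights defined over lags from -200 to 1500 ms relative to each
event onset.  Unrolling the convolution over a finite lag axis turns the
model into a (very wide) linear regression on a lagged design matrix, which
is solved by ridge regression.  The regularisation weight is selected by
rotating trials through a leave-one-trial-out cross-validation in which
single-trial TRFs of the training trials are averaged and used to predict
the held-out trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse

from .stimulus import StimulusMatrix

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "LagAxis",
    "RidgeConfig",
    "TRFSet",
    "build_lagged_design",
    "fit_ridge",
    "predict_response",
    "select_lambda",
    "estimate_trfs",
]

#: Ridge grid searched during trial-rotation cross-validation.
DEFAULT_LAMBDA_GRID = (1.0, 10.0, 100.0, 1000.0, 10000.0)


class TRFError(ValueError):
    pass


class SingularDesignError(np.linalg.LinAlgError):
    """Unregularised fit requested on a rank-deficient design."""


@dataclass(frozen=True)
class LagAxis:
    """Lag range of the TRF kernels, sampled at the analysis rate.

    Defaults give lags of -200..1500 ms at 200 Hz: 341 weights per feature.
    """

    lag_min_ms: float = -200.0
    lag_max_ms: float = 1500.0
    fs: float = 200.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise TRFError("fs must be positive")
        if self.lag_min_ms >= self.lag_max_ms:
            raise TRFError("lag_min_ms must be < lag_max_ms")

    @property
    def lags_samples(self) -> np.ndarray:
        lo = int(round(self.lag_min_ms / 1000.0 * self.fs))
        hi = int(round(self.lag_max_ms / 1000.0 * self.fs))
        return np.arange(lo, hi + 1)

    @property
    def lags_ms(self) -> np.ndarray:
        return self.lags_samples * 1000.0 / self.fs

    @property
    def n_lags(self) -> int:
        return self.lags_samples.size

    def index_of_ms(self, lag_ms: float) -> int:
        """Nearest lag index to a latency in ms."""
        return int(np.argmin(np.abs(self.lags_ms - lag_ms)))


@dataclass(frozen=True)
class RidgeConfig:
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    selected_lambda: float = 100.0

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.lambda_grid):
            raise TRFError("lambda grid values must be positive")


@dataclass
class TRFSet:
    """Per-participant kernel weights over lags for every feature/channel."""

    scheme: str
    feature_names: list[str]
    lag_axis: LagAxis
    weights: np.ndarray          # (n_channels, n_features, n_lags)
    intercept: np.ndarray        # (n_channels,)
    channel_names: tuple[str, ...] = ()
    participant_id: str = ""
    residual_variance: np.ndarray | None = None  # (n_channels,)

    def __post_init__(self) -> None:
        if self.weights.shape[2] != self.lag_axis.n_lags:
            raise TRFError("weight series length must equal the lag count")
        if self.weights.shape[1] != len(self.feature_names):
            raise TRFError("weights/feature_names mismatch")

    def kernel(self, feature: str, channel) -> np.ndarray:
        """Lag series of one feature at one channel (name or index)."""
        ch = (self.channel_names.index(channel)
              if isinstance(channel, str) else int(channel))
        return self.weights[ch, self.feature_names.index(feature)]


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def build_lagged_design(stim: StimulusMatrix, lag_axis: LagAxis
                        ) -> scipy.sparse.csr_matrix:
    """Unroll a stimulus matrix into the lagged regression design.

    Column (i, tau) of the result holds S_i(t - tau) at row t; rows outside
    the trial are zero-padded.  Columns are feature-major with lags
    ascending, shape (n_samples, n_features * n_lags).  The design is sparse
    because impulse trains are.
    """
    if abs(stim.fs - lag_axis.fs) > 1e-9:
        raise TRFError(
            f"stimulus fs {stim.fs} != lag axis fs {lag_axis.fs}")
    T = stim.n_samples
    n_feat = len(stim.feature_names)
    lags = lag_axis.lags_samples
    L = lags.size

    rows, cols = [], []
    for i in range(n_feat):
        onsets = np.flatnonzero(stim.values[i])
        if onsets.size == 0:
            continue
        r = (onsets[:, None] + lags[None, :]).ravel()
        c = (i * L + np.arange(L))[None, :].repeat(onsets.size, 0).ravel()
        ok = (r >= 0) & (r < T)
        rows.append(r[ok])
        cols.append(c[ok])
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        data = np.ones(r.size)
    else:
        r = c = np.empty(0, dtype=int)
        data = np.empty(0)
    return scipy.sparse.csr_matrix((data, (r, c)), shape=(T, n_feat * L))


# ---------------------------------------------------------------------------
# Ridge solution
# ---------------------------------------------------------------------------

def _gram(design: scipy.sparse.csr_matrix):
    """Gram blocks of [design, 1]: (X'X, X'1, T)."""
    xtx = np.asarray((design.T @ design).todense())
    xt1 = np.asarray(design.sum(axis=0)).ravel()
    return xtx, xt1, design.shape[0]


def fit_ridge(design: scipy.sparse.csr_matrix, response: np.ndarray,
              lam: float, *, fit_intercept: bool = True,
              gram=None) -> tuple[np.ndarray, np.ndarray]:
    """Solve (X'X + lam I) w = X'y with an unpenalised intercept.

    ``response`` may be (T,) or (T, n_channels); all channels share one
    factorisation.  Returns ``(weights, intercept)`` with weights shaped
    (n_channels, n_columns).  ``gram`` can carry precomputed Gram blocks
    when many fits reuse the same design.
    """
    if lam < 0:
        raise TRFError("lambda must be >= 0")
    y = np.atleast_2d(response.T).T  # (T, C)
    if y.shape[0] != design.shape[0]:
        raise TRFError("response length must equal design rows")
    xtx, xt1, T = gram if gram is not None else _gram(design)
    n_cols = xtx.shape[0]
    xty = design.T @ y  # (n_cols, C)

    if fit_intercept:
        A = np.empty((n_cols + 1, n_cols + 1))
        A[:n_cols, :n_cols] = xtx
        A[:n_cols, -1] = xt1
        A[-1, :n_cols] = xt1
        A[-1, -1] = T
        b = np.vstack([xty, y.sum(axis=0)[None, :]])
        if lam > 0:
            A[np.arange(n_cols), np.arange(n_cols)] += lam
    else:
        A = xtx.copy()
        if lam > 0:
            A[np.arange(n_cols), np.arange(n_cols)] += lam
        b = xty

    try:
        cf = scipy.linalg.cho_factor(A, lower=True, check_finite=False)
        sol = scipy.linalg.cho_solve(cf, b, check_finite=False)
    except np.linalg.LinAlgError as exc:
        if lam == 0:
            raise SingularDesignError(
                "rank-deficient design with lambda = 0") from exc
        sol = np.linalg.lstsq(A, b, rcond=None)[0]

    if fit_intercept:
        return sol[:-1].T, sol[-1]
    return sol.T, np.zeros(y.shape[1])


def _fit_trial(stim: StimulusMatrix, recording: np.ndarray,
               lag_axis: LagAxis, lam: float, *, gram=None,
               design=None) -> tuple[np.ndarray, np.ndarray]:
    """Single-trial TRF weights, shaped (C, n_features, n_lags)."""
    design = design if design is not None else build_lagged_design(stim, lag_axis)
    w, b = fit_ridge(design, recording.T, lam, gram=gram)
    C = w.shape[0]
    return w.reshape(C, len(stim.feature_names), lag_axis.n_lags), b


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_response(trfset: TRFSet, stim: StimulusMatrix) -> np.ndarray:
    """Predicted channel series sum_i sum_tau w_i(tau) S_i(t - tau).

    Equals design @ weights + intercept, shape (n_channels, n_samples).
    """
    if stim.feature_names != trfset.feature_names:
        raise TRFError("stimulus/TRF feature scheme mismatch")
    design = build_lagged_design(stim, trfset.lag_axis)
    C = trfset.weights.shape[0]
    flat = trfset.weights.reshape(C, -1)
    return np.asarray(design @ flat.T).T + trfset.intercept[:, None]


# ---------------------------------------------------------------------------
# Lambda selection by trial rotation
# ---------------------------------------------------------------------------

def select_lambda(trials, grid=DEFAULT_LAMBDA_GRID, *,
                  lag_axis: LagAxis | None = None,
                  ) -> tuple[float, dict[float, float]]:
    """Rotation (leave-one-trial-out) cross-validation over a ridge grid.

    ``trials`` is a list of ``(StimulusMatrix, recording)`` pairs for one
    participant, or a list of such lists for several participants (the MSE
    table is then averaged over participants as well as rotations and
    channels).  For each rotation the single-trial TRFs of the training
    trials are averaged and used to predict the held-out trial.  Returns
    the arg-min lambda (ties -> smaller) and the per-lambda MSE table.
    """
    grid = tuple(grid)
    if not grid:
        raise TRFError("empty lambda grid")
    participants = trials if isinstance(trials[0], list) else [trials]
    lag_axis = lag_axis or LagAxis()

    mse = {lam: [] for lam in grid}
    for ptrials in participants:
        if len(ptrials) < 2:
            raise TRFError("lambda selection needs >= 2 trials")
        designs = [build_lagged_design(s, lag_axis) for s, _ in ptrials]
        grams = [_gram(d) for d in designs]
        # per-trial, per-lambda weights; reuse the trial Gram across lambdas
        fits = [[_fit_trial(s, r, lag_axis, lam, gram=g, design=d)
                 for lam in grid]
                for (s, r), g, d in zip(ptrials, grams, designs)]
        n = len(ptrials)
        for k in range(n):
            stim_k, rec_k = ptrials[k]
            design_k = designs[k]
            for j, lam in enumerate(grid):
                w = np.mean([fits[t][j][0] for t in range(n) if t != k], axis=0)
                b = np.mean([fits[t][j][1] for t in range(n) if t != k], axis=0)
                C = w.shape[0]
                pred = (np.asarray(design_k @ w.reshape(C, -1).T).T
                        + b[:, None])
                mse[lam].append(float(np.mean((pred - rec_k) ** 2)))
    table = {lam: float(np.mean(v)) for lam, v in mse.items()}
    best = min(grid, key=lambda lam: (table[lam], lam))
    return best, table


# ---------------------------------------------------------------------------
# Participant-level estimation
# ---------------------------------------------------------------------------

def estimate_trfs(trials, lam: float, *, lag_axis: LagAxis | None = None,
                  channel_names: tuple[str, ...] = (),
                  participant_id: str = "") -> TRFSet:
    """Average single-trial ridge TRFs into one participant TRF set.

    ``trials`` is a list of ``(StimulusMatrix, recording)`` pairs; every
    trial receives equal weight.
    """
    if not trials:
        raise TRFError("at least one trial required")
    lag_axis = lag_axis or LagAxis()
    scheme = trials[0][0].scheme
    feature_names = trials[0][0].feature_names
    ws, bs, resid = [], [], []
    for stim, rec in trials:
        if stim.feature_names != feature_names:
            raise TRFError("trials disagree on feature scheme")
        design = build_lagged_design(stim, lag_axis)
        w, b = _fit_trial(stim, rec, lag_axis, lam, design=design)
        ws.append(w)
        bs.append(b)
        pred = (np.asarray(design @ w.reshape(w.shape[0], -1).T).T
                + b[:, None])
        resid.append(np.var(rec - pred, axis=1))
    return TRFSet(scheme=scheme, feature_names=list(feature_names),
                  lag_axis=lag_axis, weights=np.mean(ws, axis=0),
                  intercept=np.mean(bs, axis=0),
                  channel_names=tuple(channel_names),
                  participant_id=participant_id,
                  residual_variance=np.mean(resid, axis=0))
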