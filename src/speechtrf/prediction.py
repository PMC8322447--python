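"""Score prediction from EEG features.

Stages: Pearson screening of the participant x feature table (|r| >= 0.2
against the listening score, keeping the best electrode per feature),
z-scoring, and LASSO regression

    L(beta) = 1/(2N) sum_i (y_i - beta0 - x_i' beta)^2 + lambda sum_j |beta_j|

fit by cyclic coordinate descent with soft-thresholding (intercept
unpenalised).  The model is evaluated with an outer leave-one-participant-out
loop; inside each training split the regularisation weight is chosen from
500 evenly spaced values in [0, 5] by 10-fold cross-validation on root mean
squared error.  Feature contributions are the across-fold mean coefficients,
absolute-valued and normalised to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .components import FeatureTable

__all__ = [
    "CorrelationResult",
    "LassoModel",
    "PredictionResult",
    "correlate",
    "screen_features",
    "zscore",
    "fit_lasso",
    "lasso_path",
    "nested_cv_predict",
    "evaluate",
    "contributions",
    "default_lambda_grid",
]


class PredictionError(ValueError):
    pass


def default_lambda_grid(n: int = 500, lo: float = 0.0, hi: float = 5.0
                        ) -> np.ndarray:
    """The 500 evenly spaced LASSO weights in [0, 5] (0 included -> OLS)."""
    return np.linspace(lo, hi, n)


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    channel: str
    r: float
    ci95: tuple[float, float]
    p: float
    rho: float | None = None  # Spearman, when requested


def correlate(x, y, method: str = "pearson", *, feature: str = "",
              channel: str = "") -> CorrelationResult:
    """Pearson (or Spearman) correlation with Fisher-z 95% CI and p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise PredictionError("correlate needs equal-length inputs, n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise PredictionError("correlation undefined for zero-variance input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        rho = None
    elif method == "spearman":
        res = stats.spearmanr(x, y)
        r, p = float(res.statistic), float(res.pvalue)
        rho = r
    else:
        raise PredictionError(f"unknown method {method!r}")
    n = x.size
    zr = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    ci = (float(np.tanh(zr - half)), float(np.tanh(zr + half)))
    return CorrelationResult(feature, channel, float(r), ci, float(p), rho)


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def _split_channel(column: str) -> tuple[str, str]:
    """Split 'feature....channel' column names on the final dot."""
    base, _, channel = column.rpartition(".")
    return (base, channel) if base else (column, "")


def screen_features(table: FeatureTable | pd.DataFrame,
                    threshold: float = 0.2, *,
                    use_abs: bool = True) -> list[CorrelationResult]:
    """Keep features correlating with the score at |r| >= threshold.

    Columns sharing everything but the trailing channel label are one
    feature measured at several electrodes; among the channels passing the
    (inclusive) threshold only the one with the highest |r| survives
    (``use_abs=False`` ranks by signed r instead; ties fall back to column
    order).  Returns one CorrelationResult per selected feature.
    """
    df = table.table if isinstance(table, FeatureTable) else table
    if "score" not in df.columns:
        raise PredictionError("table must contain a 'score' column")
    y = df["score"].to_numpy()

    by_feature: dict[str, list[CorrelationResult]] = {}
    for col in df.columns:
        if col == "score":
            continue
        x = df[col].to_numpy()
        if np.std(x) == 0:
            continue
        base, channel = _split_channel(col)
        res = correlate(x, y, feature=base, channel=channel)
        by_feature.setdefault(base, []).append(res)

    selected = []
    for base, results in by_feature.items():
        passing = [r for r in results if abs(r.r) >= threshold]
        if not passing:
            continue
        key = (lambda r: abs(r.r)) if use_abs else (lambda r: r.r)
        best = max(passing, key=key)  # max keeps the first on exact ties
        selected.append(best)
    return selected


def selected_columns(selected: list[CorrelationResult]) -> list[str]:
    return [f"{r.feature}.{r.channel}" if r.channel else r.feature
            for r in selected]


def zscore(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Standardise the given columns to mean 0, SD 1 (ddof=1) over all rows.

    Full-sample standardisation mirrors the published pipeline; for a
    leakage-free variant standardise inside each training split instead.
    """
    out = df.copy()
    for c in columns:
        sd = out[c].std(ddof=1)
        if sd == 0 or np.isnan(sd):
            raise PredictionError(f"constant column {c!r} cannot be z-scored")
        out[c] = (out[c] - out[c].mean()) / sd
    return out


# ---------------------------------------------------------------------------
# LASSO by cyclic coordinate descent
# ---------------------------------------------------------------------------

@dataclass
class LassoModel:
    beta0: float
    beta: np.ndarray
    lam: float
    n_train: int
    feature_names: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.beta0 + np.asarray(X, dtype=float) @ self.beta


def _cd_lasso(G: np.ndarray, c: np.ndarray, lam: float, beta: np.ndarray,
              tol: float = 1e-7, max_sweeps: int = 100000) -> np.ndarray:
    """Coordinate descent on the Gram form of the centred LASSO problem.

    G = X'X / N, c = X'y / N for column-centred X and centred y.  Updates
    beta_j <- S(c_j - sum_{k != j} G_jk beta_k, lam) / G_jj.
    """
    M = beta.size
    g = G @ beta  # maintained as G beta
    diag = np.diag(G).copy()
    diag[diag == 0] = 1.0
    for _ in range(max_sweeps):
        delta_max = 0.0
        for j in range(M):
            rho = c[j] - g[j] + G[j, j] * beta[j]
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / diag[j]
            d = new - beta[j]
            if d != 0.0:
                beta[j] = new
                g += G[:, j] * d
                delta_max = max(delta_max, abs(d))
        if delta_max < tol:
            return beta
    raise PredictionError(
        f"coordinate descent did not converge (lam={lam}, "
        f"last max step {delta_max:.3e})")


def fit_lasso(X: np.ndarray, y: np.ndarray, lam: float, *,
              feature_names: list[str] | None = None,
              tol: float = 1e-7) -> LassoModel:
    """Minimise 1/(2N)||y - beta0 - X beta||^2 + lam ||beta||_1.

    The intercept is unpenalised.  ``lam = 0`` is solved exactly as ordinary
    least squares (pseudoinverse when rank-deficient).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise PredictionError("X rows must match len(y)")
    if lam < 0:
        raise PredictionError("lambda must be >= 0")
    N, M = X.shape
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym

    if lam == 0:
        beta = np.linalg.lstsq(Xc, yc, rcond=None)[0]
    else:
        G = Xc.T @ Xc / N
        c = Xc.T @ yc / N
        beta = _cd_lasso(G, c, lam, np.zeros(M), tol=tol)
    beta0 = float(ym - xm @ beta)
    return LassoModel(beta0=beta0, beta=beta, lam=float(lam), n_train=N,
                      feature_names=list(feature_names or []))


def lasso_path(X: np.ndarray, y: np.ndarray, grid: np.ndarray, *,
               tol: float = 1e-7) -> np.ndarray:
    """Solutions for every lambda in ``grid`` (warm-started, descending).

    Returns betas shaped (len(grid), M) in the grid's order; intercepts
    follow from beta0 = mean(y) - mean(X) @ beta.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    N, M = X.shape
    xm = X.mean(axis=0)
    Xc = X - xm
    yc = y - y.mean()
    G = Xc.T @ Xc / N
    c = Xc.T @ yc / N

    order = np.argsort(grid)[::-1]  # large lambda first for warm starts
    betas = np.zeros((grid.size, M))
    beta = np.zeros(M)
    for idx in order:
        lam = grid[idx]
        if lam == 0:
            betas[idx] = np.linalg.lstsq(Xc, yc, rcond=None)[0]
        else:
            beta = _cd_lasso(G, c, float(lam), beta.copy(), tol=tol)
            betas[idx] = beta
    return betas


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    predicted: np.ndarray            # out-of-fold predicted scores
    true: np.ndarray
    r: float
    r_ci95: tuple[float, float]
    r_p: float
    mad: float                       # mean absolute difference
    mad_sd: float
    rmse: float
    fold_lambdas: np.ndarray         # selected lambda per outer fold
    fold_train_rmse: np.ndarray
    models: list[LassoModel]
    contributions: dict[str, float] = field(default_factory=dict)


def _fold_assignment(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Deterministic shuffled assignment of n items to k folds."""
    folds = np.arange(n) % k
    rng.shuffle(folds)
    return folds


def nested_cv_predict(table: FeatureTable | pd.DataFrame,
                      feature_columns: list[str], *,
                      grid: np.ndarray | None = None,
                      inner_folds: int = 10, seed: int = 0,
                      tol: float = 1e-7) -> PredictionResult:
    """Leave-one-participant-out prediction with inner 10-fold lambda tuning.

    For each held-out participant, every lambda on the grid is scored by
    RMSE over ``inner_folds`` folds of the training split; the minimiser
    (ties -> smaller lambda) is refit on the whole training split and the
    held-out score predicted.  Fold assignment is a deterministic shuffle
    derived from ``seed``.
    """
    df = table.table if isinstance(table, FeatureTable) else table
    grid = default_lambda_grid() if grid is None else np.asarray(grid, float)
    X = df[feature_columns].to_numpy(dtype=float)
    y = df["score"].to_numpy(dtype=float)
    n = y.size
    if n < inner_folds + 1:
        raise PredictionError(
            f"need at least {inner_folds + 1} participants, got {n}")

    predicted = np.empty(n)
    fold_lams = np.empty(n)
    fold_rmse = np.empty(n)
    models: list[LassoModel] = []
    master = np.random.default_rng(seed)
    fold_seeds = master.integers(0, 2 ** 31 - 1, size=n)

    for i in range(n):
        tr = np.arange(n) != i
        Xtr, ytr = X[tr], y[tr]
        inner_rng = np.random.default_rng(fold_seeds[i])
        folds = _fold_assignment(Xtr.shape[0], inner_folds, inner_rng)
        sse = np.zeros(grid.size)
        count = 0
        for f in range(inner_folds):
            val = folds == f
            if not val.any() or val.all():
                continue
            betas = lasso_path(Xtr[~val], ytr[~val], grid, tol=tol)
            b0 = ytr[~val].mean() - Xtr[~val].mean(axis=0) @ betas.T
            preds = Xtr[val] @ betas.T + b0  # (n_val, n_lambda)
            sse += ((preds - ytr[val, None]) ** 2).sum(axis=0)
            count += val.sum()
        rmse_by_lam = np.sqrt(sse / count)
        best = int(np.argmin(rmse_by_lam))  # first minimum -> smaller lambda
        lam = float(grid[best])
        model = fit_lasso(Xtr, ytr, lam, feature_names=feature_columns,
                          tol=tol)
        predicted[i] = model.predict(X[i][None, :])[0]
        fold_lams[i] = lam
        fold_rmse[i] = float(np.sqrt(np.mean((model.predict(Xtr) - ytr) ** 2)))
        models.append(model)

    metrics = evaluate(y, predicted)
    contrib = contributions(models)
    return PredictionResult(
        predicted=predicted, true=y, r=metrics["r"], r_ci95=metrics["r_ci95"],
        r_p=metrics["p"], mad=metrics["mad"], mad_sd=metrics["mad_sd"],
        rmse=metrics["rmse"], fold_lambdas=fold_lams,
        fold_train_rmse=fold_rmse, models=models, contributions=contrib)


def evaluate(true: np.ndarray, predicted: np.ndarray) -> dict:
    """Pearson r (with CI), mean absolute difference +- SD, and RMSE."""
    true = np.asarray(true, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if true.size != predicted.size:
        raise PredictionError("length mismatch")
    absdiff = np.abs(true - predicted)
    if np.std(predicted) == 0 or np.std(true) == 0:
        r, ci, p = float("nan"), (float("nan"), float("nan")), float("nan")
    else:
        res = correlate(true, predicted)
        r, ci, p = res.r, res.ci95, res.p
    return {"r": r, "r_ci95": ci, "p": p,
            "mad": float(absdiff.mean()),
            "mad_sd": float(absdiff.std(ddof=1)) if absdiff.size > 1 else 0.0,
            "rmse": float(np.sqrt(np.mean((true - predicted) ** 2)))}


def contributions(models: list[LassoModel]) -> dict[str, float]:
    """Mean coefficient across models -> |.| -> normalised to max 1."""
    if not models:
        raise PredictionError("contributions need at least one model")
    names = models[0].feature_names or \
        [f"f{j}" for j in range(models[0].beta.size)]
    mean_beta = np.mean([m.beta for m in models], axis=0)
    mag = np.abs(mean_beta)
    top = mag.max()
    if top > 0:
        mag = mag / top
    return dict(zip(names, mag.astype(float)))
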