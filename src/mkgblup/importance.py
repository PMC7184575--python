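"""Trait-importance ranking by penalized regression.

Grain yield is regressed on the standardized physiological-trait LSmeans
under the elastic-net objective

    (1 / 2n) * ||y - X beta||^2 + lambda * (alpha * ||beta||_1
                                            + (1 - alpha) * ||beta||_2^2 / 2)

over a grid of (alpha, lambda); the pair minimizing the repeated
cross-validated mean squared error is chosen, the model refit on all data,
and each trait's importance reported as 100 * |beta| / max |beta|.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ImportanceError(ValueError):
    pass


def default_lambda_grid(X: np.ndarray, y: np.ndarray, n_points: int = 50, decades: float = 4.0) -> np.ndarray:
    """Log-spaced grid from lambda_max (smallest penalty zeroing every LASSO
    coefficient, max |X'y| / n) down the given number of decades."""
    n = X.shape[0]
    lam_max = float(np.max(np.abs(X.T @ (y - y.mean())))) / n
    lam_max = max(lam_max, 1e-6)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_points)


@dataclass
class ImportanceConfig:
    alpha_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    lambda_grid: tuple[float, ...] | None = None  # default derived from the data
    cv_folds: int = 10
    cv_repeats: int = 20
    seed: int = 0
    dth_corrected: bool = False

    def __post_init__(self) -> None:
        if len(self.alpha_grid) == 0:
            raise ImportanceError("alpha grid is empty")
        if self.cv_folds < 2:
            raise ImportanceError("need at least 2 CV folds")


@dataclass
class ImportanceResult:
    alpha: float
    lam: float
    coefficients: pd.Series  # standardized scale
    importance: pd.Series  # scaled to max 100
    cv_mse: pd.DataFrame  # columns alpha, lam, mse
    dth_corrected: bool


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def fit_elastic_net(X, y, alpha: float, lam: float, tol: float = 1e-7) -> np.ndarray:
    """Elastic-net coefficients for centered y and standardized X.

    ``alpha`` is the L1 mixing weight, ``lam`` the penalty strength, in the
    (1/2n) RSS parameterization.  Pure ridge (alpha = 0) is solved in
    closed form; otherwise coordinate descent (scikit-learn) is used with
    convergence tolerance on the coefficient updates.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ImportanceError("non-finite values in the regression inputs")
    n, p = X.shape
    yc = y - y.mean()
    if lam == 0.0:
        beta, *_ = np.linalg.lstsq(X, yc, rcond=None)
        return beta
    if alpha == 0.0:
        # closed-form ridge: minimize RSS + n * lam * ||beta||^2
        A = X.T @ X + n * lam * np.eye(p)
        return np.linalg.solve(A, X.T @ yc)
    from sklearn.linear_model import ElasticNet

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ElasticNet(
            alpha=lam, l1_ratio=alpha, fit_intercept=False, tol=tol, max_iter=100_000
        )
        model.fit(X, yc)
    return model.coef_.copy()


def _penalty_path(Xt: np.ndarray, yc: np.ndarray, alpha: float, lambdas: np.ndarray) -> np.ndarray:
    """Coefficients for every lambda at one alpha (p x n_lambdas).

    Uses the coordinate-descent regularization path for alpha > 0 and the
    eigendecomposition closed form for ridge.
    """
    n, p = Xt.shape
    if alpha == 0.0:
        w, V = np.linalg.eigh(Xt.T @ Xt)
        Xty = Xt.T @ yc
        VtXty = V.T @ Xty
        return V @ (VtXty[:, None] / (w[:, None] + n * lambdas[None, :]))
    from sklearn.linear_model import enet_path

    order = np.argsort(lambdas)[::-1]  # path solvers want decreasing penalties
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, coefs, _ = enet_path(
            Xt, yc, l1_ratio=alpha, alphas=lambdas[order], tol=1e-7
        )
    out = np.empty((p, len(lambdas)))
    out[:, order] = coefs
    return out


def tune_and_rank(
    X: pd.DataFrame | np.ndarray,
    y,
    config: ImportanceConfig | None = None,
    trait_names: list[str] | None = None,
    dth=None,
) -> ImportanceResult:
    """Repeated k-fold CV over the (alpha, lambda) grid, refit at the MSE
    minimizer, and report scaled absolute coefficients as importances.

    When ``config.dth_corrected`` is set, days-to-heading is regressed out
    of y before tuning (the covariate analogue of DTH-corrected LSmeans);
    ``dth`` must then be supplied.
    """
    config = config or ImportanceConfig()
    if isinstance(X, pd.DataFrame):
        trait_names = [str(c) for c in X.columns]
        X = X.to_numpy(float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ImportanceError("need at least 2 traits to rank")
    if n <= config.cv_folds:
        raise ImportanceError("need more observations than CV folds")
    if trait_names is None:
        trait_names = [f"x{j}" for j in range(p)]

    if config.dth_corrected:
        if dth is None:
            raise ImportanceError("dth values required when dth_corrected")
        d = np.asarray(dth, dtype=float)
        d = d - d.mean()
        coef = float(d @ (y - y.mean())) / float(d @ d)
        y = y - coef * d

    Xs, _, _ = _standardize(X)
    yc = y - y.mean()
    lambdas = (
        np.asarray(config.lambda_grid, dtype=float)
        if config.lambda_grid is not None
        else default_lambda_grid(Xs, yc)
    )
    if (lambdas <= 0).any():
        raise ImportanceError("lambda grid must be positive")
    alphas = np.asarray(config.alpha_grid, dtype=float)
    # glmnet-style per-alpha scaling so each path reaches the null model
    lam_by_alpha = [
        lambdas if a == 0.0 or config.lambda_grid is not None else lambdas / max(a, 1e-3)
        for a in alphas
    ]

    rng = np.random.default_rng(config.seed)
    sse = np.zeros((len(alphas), len(lambdas)))
    n_pred = 0
    for _ in range(config.cv_repeats):
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[perm] = np.arange(n) % config.cv_folds
        for k in range(config.cv_folds):
            test = fold_of == k
            train = ~test
            Xt, mu_t, sd_t = _standardize(X[train])
            yt = y[train]
            Xv = (X[test] - mu_t) / sd_t
            for a, alpha in enumerate(alphas):
                # betas: p x n_lambdas, one column per penalty
                betas = _penalty_path(Xt, yt - yt.mean(), float(alpha), lam_by_alpha[a])
                pred = yt.mean() + Xv @ betas
                sse[a] += np.sum((y[test][:, None] - pred) ** 2, axis=0)
            n_pred += int(test.sum())
    mse = sse / n_pred
    a_best, l_best = np.unravel_index(np.argmin(mse), mse.shape)
    alpha_star = float(alphas[a_best])
    lam_star = float(lam_by_alpha[a_best][l_best])
    beta = fit_elastic_net(Xs, y, alpha_star, lam_star)
    absb = np.abs(beta)
    if absb.max() == 0:
        warnings.warn("all coefficients zero at the selected penalty", stacklevel=2)
        importance = np.zeros(p)
    else:
        importance = 100.0 * absb / absb.max()
    surface = pd.DataFrame(
        [
            {"alpha": float(a), "lam": float(lam_by_alpha[i][j]), "mse": float(mse[i, j])}
            for i, a in enumerate(alphas)
            for j in range(len(lambdas))
        ]
    )
    logger.info("tune_and_rank: chose alpha=%.2f lambda=%.4g", alpha_star, lam_star)
    return ImportanceResult(
        alpha=alpha_star,
        lam=lam_star,
        coefficients=pd.Series(beta, index=trait_names, name="beta"),
        importance=pd.Series(importance, index=trait_names, name="importance").sort_values(
            ascending=False
        ),
        cv_mse=surface,
        dth_corrected=config.dth_corrected,
    )
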