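"""L1-penalized factor ranking with cross-validated lambda (1-SE rule).

All factors and retained covariates enter one penalized least-squares model
of the resilience outcome. The penalty lambda is chosen by K-fold
cross-validation as the LARGEST lambda whose mean CV error lies within one
standard error of the minimum (the simplest model of comparable accuracy).
Explained variance is summarized by the deviance ratio, 1 - RSS/RSS0 for
Gaussian fits. Selection stability is assessed by repeating the whole
CV + 1-SE pipeline with re-randomized fold assignments and recording, per
term, the fraction of runs in which its coefficient is nonzero at that
run's optimal lambda. Factor ranks order the absolute standardized
coefficients at the optimal lambda.

The path solver is coordinate descent (scikit-learn's ``lasso_path``) under
the objective ``(1/2n) ||y - Xb||^2 + lambda ||b||_1`` with an unpenalized
intercept handled by centering; the grid, CV, selection, deviance ratio,
stability repeats and ranking live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

__all__ = [
    "LassoResult",
    "LassoFactorRanker",
    "fit_lasso_path",
    "select_lambda_1se",
    "deviance_ratio",
    "stability_selection",
    "rank_factors",
]


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    if (scale == 0).any():
        raise ValueError("zero-variance column in penalized design")
    return (X - mean) / scale, mean, scale


def default_lambda_grid(X_std: np.ndarray, y_centered: np.ndarray,
                        n_points: int = 100, ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced grid from lambda_max (null model) down by ``ratio``."""
    n = len(y_centered)
    lam_max = float(np.abs(X_std.T @ y_centered).max() / n)
    if lam_max <= 0:
        lam_max = 1.0
    return np.logspace(np.log10(lam_max), np.log10(lam_max * ratio), n_points)


def fit_lasso_path(X, y, lambdas) -> np.ndarray:
    """Coefficient path (n_features x n_lambdas) on the given design.

    The design is used as passed (standardize upstream); y is centered
    internally so the intercept is unpenalized. An exact zero lambda is
    solved by ordinary least squares.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("penalized design must be a nonempty 2-D array")
    y = np.asarray(y, dtype=float).reshape(-1)
    yc = y - y.mean()
    lambdas = np.asarray(lambdas, dtype=float)
    pos = lambdas > 0
    coefs = np.zeros((X.shape[1], len(lambdas)))
    if pos.any():
        # lasso_path expects a descending grid
        order = np.argsort(lambdas[pos])[::-1]
        grid = lambdas[pos][order]
        _, path, _ = lasso_path(X, yc, alphas=grid)
        out = np.empty_like(path)
        out[:, order] = path
        coefs[:, pos] = out
    if (~pos).any():
        ols = np.linalg.lstsq(np.column_stack([np.ones(len(yc)), X]), yc, rcond=None)[0][1:]
        coefs[:, ~pos] = ols[:, None]
    return coefs


def select_lambda_1se(cv_means, cv_ses, lambdas) -> float:
    """Largest lambda whose mean CV error <= min(mean) + SE at the minimizer."""
    means = np.asarray(cv_means, dtype=float)
    ses = np.asarray(cv_ses, dtype=float)
    lams = np.asarray(lambdas, dtype=float)
    if means.shape != ses.shape or means.shape != lams.shape:
        raise ValueError("cv_means, cv_ses and lambdas must align")
    finite = np.isfinite(means)
    if not finite.any():
        raise ValueError("all CV means are NaN")
    i_min = int(np.nanargmin(means))
    cutoff = means[i_min] + ses[i_min]
    eligible = finite & (means <= cutoff)
    return float(lams[eligible].max())


def deviance_ratio(y, y_pred) -> float:
    """1 - RSS/RSS0 against the intercept-only model, clipped to [0, 1]."""
    y = np.asarray(y, dtype=float).reshape(-1)
    y_pred = np.asarray(y_pred, dtype=float).reshape(-1)
    rss0 = float(((y - y.mean()) ** 2).sum())
    if rss0 == 0:
        raise ValueError("outcome has zero variance; deviance ratio undefined")
    rss = float(((y - y_pred) ** 2).sum())
    return float(np.clip(1.0 - rss / rss0, 0.0, 1.0))


def rank_factors(coefficients: dict[str, float]) -> dict[str, int]:
    """Rank 1 = largest |coefficient|; ties broken by factor name order."""
    items = sorted(coefficients.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    return {name: i + 1 for i, (name, _) in enumerate(items)}


@dataclass
class LassoResult:
    lambdas: np.ndarray
    coef_path: pd.DataFrame  # term x lambda
    cv_means: np.ndarray
    cv_ses: np.ndarray
    lambda_min: float
    lambda_opt: float
    coefficients: dict[str, float]
    deviance_ratio: float
    selection_frequency: dict[str, float] = field(default_factory=dict)
    factor_ranks: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "lambdas": self.lambdas.tolist(),
            "cv_means": self.cv_means.tolist(),
            "cv_ses": self.cv_ses.tolist(),
            "lambda_min": self.lambda_min,
            "lambda_opt": self.lambda_opt,
            "coefficients": self.coefficients,
            "deviance_ratio": self.deviance_ratio,
            "selection_frequency": self.selection_frequency,
            "factor_ranks": self.factor_ranks,
        }


class LassoFactorRanker(BaseEstimator):
    """Penalized multi-variable ranking of resilience factors.

    Parameters
    ----------
    n_folds : int
        Cross-validation folds (default 10).
    n_lambdas, lambda_ratio : grid resolution and depth below lambda_max.
    random_state : seed for the fold shuffles.

    After ``fit(X, y)`` with a numeric DataFrame X: ``lambdas_``,
    ``coef_path_``, ``cv_means_``, ``cv_ses_``, ``lambda_min_``,
    ``lambda_opt_``, ``coef_`` (standardized scale, dict), and
    ``deviance_ratio_``.
    """

    def __init__(
        self,
        n_folds: int = 10,
        n_lambdas: int = 100,
        lambda_ratio: float = 1e-3,
        random_state: int | None = None,
    ):
        self.n_folds = n_folds
        self.n_lambdas = n_lambdas
        self.lambda_ratio = lambda_ratio
        self.random_state = random_state

    def _cv_curve(
        self,
        X_std: np.ndarray,
        yc: np.ndarray,
        lambdas: np.ndarray,
        rng: np.random.Generator,
    ) -> tuple[np.ndarray, np.ndarray]:
        kf = KFold(
            n_splits=self.n_folds,
            shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        fold_mse = np.empty((self.n_folds, len(lambdas)))
        for k, (tr, va) in enumerate(kf.split(X_std)):
            coefs = fit_lasso_path(X_std[tr], yc[tr], lambdas)
            mu = yc[tr].mean()
            pred = X_std[va] @ coefs + mu
            fold_mse[k] = ((yc[va][:, None] - pred) ** 2).mean(axis=0)
        means = fold_mse.mean(axis=0)
        ses = fold_mse.std(axis=0, ddof=1) / np.sqrt(self.n_folds)
        return means, ses

    def fit(self, X: pd.DataFrame, y) -> "LassoFactorRanker":
        X = pd.DataFrame(X)
        if X.shape[1] == 0:
            raise ValueError("empty penalized design")
        if len(X) < self.n_folds:
            raise ValueError(
                f"need at least n_folds={self.n_folds} rows, got {len(X)}"
            )
        self.feature_names_ = list(X.columns)
        Xs, self.mean_, self.scale_ = _standardize(X.to_numpy(dtype=float))
        y = np.asarray(y, dtype=float).reshape(-1)
        yc = y - y.mean()
        self._Xs, self._yc, self._y = Xs, yc, y

        lambdas = default_lambda_grid(Xs, yc, self.n_lambdas, self.lambda_ratio)
        rng = np.random.default_rng(self.random_state)
        means, ses = self._cv_curve(Xs, yc, lambdas, rng)
        self.lambdas_ = lambdas
        self.cv_means_, self.cv_ses_ = means, ses
        self.lambda_min_ = float(lambdas[int(np.nanargmin(means))])
        self.lambda_opt_ = select_lambda_1se(means, ses, lambdas)

        path = fit_lasso_path(Xs, yc, lambdas)
        self.coef_path_ = pd.DataFrame(path, index=self.feature_names_, columns=lambdas)
        i_opt = int(np.argmin(np.abs(lambdas - self.lambda_opt_)))
        at_opt = path[:, i_opt]
        self.coef_ = {name: float(b) for name, b in zip(self.feature_names_, at_opt)}
        self.deviance_ratio_ = deviance_ratio(yc, Xs @ at_opt)
        self._rng = rng
        return self

    def rank(self, factors: list[str] | None = None) -> dict[str, int]:
        names = factors if factors is not None else self.feature_names_
        return rank_factors({n: self.coef_[n] for n in names})

    def stability(
        self, runs: int = 800, resample_rows: bool = False
    ) -> dict[str, float]:
        """Selection frequency per term over re-randomized CV repeats."""
        return stability_selection(self, runs=runs, resample_rows=resample_rows)

    def result(self, factors: list[str] | None = None) -> LassoResult:
        return LassoResult(
            lambdas=self.lambdas_,
            coef_path=self.coef_path_,
            cv_means=self.cv_means_,
            cv_ses=self.cv_ses_,
            lambda_min=self.lambda_min_,
            lambda_opt=self.lambda_opt_,
            coefficients=self.coef_,
            deviance_ratio=self.deviance_ratio_,
            factor_ranks=self.rank(factors),
        )


def stability_selection(
    fitted: LassoFactorRanker, runs: int = 800, resample_rows: bool = False
) -> dict[str, float]:
    """Fraction of repeated CV + 1-SE fits selecting each term.

    Each run re-randomizes the fold assignment (optionally also bootstrap
    resamples the rows), re-selects lambda by the 1-SE rule, and counts a
    term as selected if its coefficient at that run's optimal lambda is
    nonzero. Reproducible from the ranker's random_state.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    Xs, yc = fitted._Xs, fitted._yc
    lambdas = fitted.lambdas_
    rng = np.random.default_rng(
        None if fitted.random_state is None else fitted.random_state + 1
    )
    counts = np.zeros(len(fitted.feature_names_))
    for _ in range(runs):
        if resample_rows:
            idx = rng.integers(0, len(yc), size=len(yc))
            Xr, yr = Xs[idx], yc[idx]
        else:
            Xr, yr = Xs, yc
        means, ses = fitted._cv_curve(Xr, yr, lambdas, rng)
        lam_opt = select_lambda_1se(means, ses, lambdas)
        path = fit_lasso_path(Xr, yr, np.array([lam_opt]))
        counts += (np.abs(path[:, 0]) > 0).astype(float)
    freq = counts / runs
    return {name: float(f) for name, f in zip(fitted.feature_names_, freq)}
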