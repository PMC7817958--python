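"""Covariate screening and the directed resilience-factor hypothesis tests.

Covariates are screened univariately against the resilience outcome with a
likelihood-ratio test (retained at p < 0.2). Each of the nine directed
hypotheses is then tested in its own multiple regression of the outcome on
the retained covariates plus the factor, reporting the factor's coefficient
with a 99% Wald confidence interval, its two-tailed p-value, and the
adjusted-R-squared increase over the covariates-only model. Family-wise
comparison uses the Bonferroni threshold alpha / m (0.01 / 9 = 0.0011).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "CovariateScreener",
    "FactorTestResult",
    "screen_covariates",
    "test_factor",
    "bonferroni_threshold",
    "expand_terms",
    "CollinearityError",
]


class CollinearityError(ValueError):
    """The design matrix is rank-deficient; names the offending terms."""


def expand_terms(df: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Build a numeric design block: numerics pass through, categoricals
    become treatment-coded indicators with the most frequent level as the
    reference."""
    blocks: list[pd.DataFrame] = []
    for term in terms:
        col = df[term]
        if pd.api.types.is_numeric_dtype(col):
            blocks.append(col.astype(float).to_frame(term))
        else:
            reference = col.value_counts().idxmax()
            levels = [l for l in col.dropna().unique() if l != reference]
            dummies = pd.DataFrame(
                {f"{term}[{lvl}]": (col == lvl).astype(float) for lvl in sorted(map(str, levels))},
                index=df.index,
            )
            blocks.append(dummies)
    if not blocks:
        return pd.DataFrame(index=df.index)
    return pd.concat(blocks, axis=1)


def _check_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    if X.shape[1] == 0:
        return
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [design.columns[i] for i in np.flatnonzero(diag <= tol)]
    if bad:
        raise CollinearityError(f"collinear terms in design: {', '.join(map(str, bad))}")


def _fit_ols(y: np.ndarray, design: pd.DataFrame):
    X = sm.add_constant(design, has_constant="add")
    return sm.OLS(y, X).fit()


def screen_covariates(
    data: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Univariate likelihood-ratio screen of each covariate against outcome.

    For each covariate, LR = 2 * (ll_with - ll_null) is referred to a
    chi-squared distribution with df = number of added terms; the covariate
    is retained iff p < threshold. A covariate observed at a single level is
    flagged unscreenable (df = 0) and not retained.
    """
    rows = []
    for cov in covariates:
        sub = data[[outcome, cov]].dropna()
        y = sub[outcome].to_numpy(dtype=float)
        block = expand_terms(sub, [cov])
        df_added = block.shape[1]
        if df_added == 0 or (block.nunique() <= 1).all():
            rows.append(
                {"covariate": cov, "lr": np.nan, "df": 0, "p": np.nan,
                 "retained": False, "note": "unscreenable (single level)"}
            )
            continue
        null_fit = _fit_ols(y, pd.DataFrame(index=sub.index))
        full_fit = _fit_ols(y, block)
        lr = 2.0 * (full_fit.llf - null_fit.llf)
        p = float(stats.chi2.sf(lr, df_added))
        rows.append(
            {"covariate": cov, "lr": float(lr), "df": df_added, "p": p,
             "retained": bool(p < threshold), "note": ""}
        )
    return pd.DataFrame(rows).set_index("covariate")


class CovariateScreener(BaseEstimator):
    """sklearn-style wrapper around the LR screen.

    After ``fit(X, y)`` (X a DataFrame of candidate covariates),
    ``results_`` holds the per-covariate LR table and ``retained_`` the
    covariate names surviving at ``threshold``.
    """

    def __init__(self, threshold: float = 0.2):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y) -> "CovariateScreener":
        data = X.copy()
        data["__outcome__"] = np.asarray(y, dtype=float)
        self.results_ = screen_covariates(
            data, "__outcome__", list(X.columns), threshold=self.threshold
        )
        self.retained_ = [c for c in X.columns if self.results_.loc[c, "retained"]]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.retained_]


@dataclass
class FactorTestResult:
    """One directed hypothesis test: RES ~ covariates + factor."""

    factor: str
    beta: float
    se: float
    p: float
    ci_low: float
    ci_high: float
    level: float
    adj_r2_full: float
    adj_r2_covariates: float
    delta_adj_r2: float
    n: int
    loglik: float

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "beta": self.beta,
            "se": self.se,
            "p": self.p,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "adj_r2_full": self.adj_r2_full,
            "adj_r2_covariates": self.adj_r2_covariates,
            "delta_adj_r2": self.delta_adj_r2,
            "n": self.n,
            "loglik": self.loglik,
        }


def test_factor(
    data: pd.DataFrame,
    outcome: str,
    factor: str,
    covariates: list[str],
    level: float = 0.99,
) -> FactorTestResult:
    """Multiple regression of outcome on screened covariates plus a factor.

    Returns the factor's coefficient with a Wald CI at ``level``, two-tailed
    p-value, and the adjusted-R-squared increase over the covariates-only
    model fitted on the same rows.
    """
    cols = [outcome, factor] + list(covariates)
    sub = data[cols].dropna()
    y = sub[outcome].to_numpy(dtype=float)
    cov_block = expand_terms(sub, list(covariates))
    full_block = pd.concat(
        [cov_block, sub[factor].astype(float).to_frame(factor)], axis=1
    )
    _check_rank(sm.add_constant(full_block, has_constant="add"))
    cov_fit = _fit_ols(y, cov_block)
    full_fit = _fit_ols(y, full_block)
    alpha = 1.0 - level
    ci = full_fit.conf_int(alpha=alpha)
    return FactorTestResult(
        factor=factor,
        beta=float(full_fit.params[factor]),
        se=float(full_fit.bse[factor]),
        p=float(full_fit.pvalues[factor]),
        ci_low=float(ci.loc[factor, 0]),
        ci_high=float(ci.loc[factor, 1]),
        level=level,
        adj_r2_full=float(full_fit.rsquared_adj),
        adj_r2_covariates=float(cov_fit.rsquared_adj),
        delta_adj_r2=float(full_fit.rsquared_adj - cov_fit.rsquared_adj),
        n=int(full_fit.nobs),
        loglik=float(full_fit.llf),
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise comparison threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return alpha / m
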