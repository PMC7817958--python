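"""Residual-based resilience quantification.

Resilience is operationalized as an outcome: maintained mental health
despite stressor exposure. The exposure->symptom regression fitted on the
analysis sample is the normative stressor reactivity; a participant's
resilience score is the INVERSE residual, predicted minus observed symptoms,
so that lying below the curve (fewer symptoms than the norm predicts, i.e.
under-reactivity) yields a positive score. By construction the scores are
exposure-corrected: in the linear form they have mean zero and zero sample
correlation with the exposure variable on the fitting sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ResilienceScorer",
    "fit_normative_curve",
    "residual_resilience",
    "compute_all",
]


class ResilienceScorer(RegressorMixin, BaseEstimator):
    """Normative exposure->symptom regression with inverse-residual scores.

    Parameters
    ----------
    form : {'linear', 'quadratic'}
        Shape of the normative curve. The linear form is the default; the
        quadratic form adds an E^2 term for sensitivity analysis.

    Attributes
    ----------
    coef_ : ndarray
        Regression coefficients (intercept first).
    r_squared_ : float
        Coefficient of determination of the normative fit.
    n_ : int
        Number of participants the curve was fitted on.
    """

    def __init__(self, form: str = "linear"):
        self.form = form

    def _design(self, exposure: np.ndarray) -> np.ndarray:
        cols = [np.ones_like(exposure), exposure]
        if self.form == "quadratic":
            cols.append(exposure**2)
        elif self.form != "linear":
            raise ValueError(f"unknown form {self.form!r}; use 'linear' or 'quadratic'")
        return np.column_stack(cols)

    def fit(self, X, y) -> "ResilienceScorer":
        exposure = np.asarray(X, dtype=float).reshape(-1)
        symptoms = np.asarray(y, dtype=float).reshape(-1)
        if exposure.shape != symptoms.shape:
            raise ValueError("exposure and symptom vectors differ in length")
        if len(exposure) < 3:
            raise ValueError("need at least 3 participants to fit the normative curve")
        if exposure.std() == 0:
            raise ValueError("exposure is constant; normative curve undefined")
        design = self._design(exposure)
        coef, _, rank, _ = np.linalg.lstsq(design, symptoms, rcond=None)
        if rank < design.shape[1]:
            raise ValueError("degenerate design for the normative curve")
        self.coef_ = coef
        fitted = design @ coef
        ss_res = float(((symptoms - fitted) ** 2).sum())
        ss_tot = float(((symptoms - symptoms.mean()) ** 2).sum())
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.n_ = len(exposure)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        exposure = np.asarray(X, dtype=float).reshape(-1)
        return self._design(exposure) @ self.coef_

    def resilience(self, X, y) -> np.ndarray:
        """Inverse residuals: predicted minus observed symptom totals."""
        return self.predict(X) - np.asarray(y, dtype=float).reshape(-1)


def fit_normative_curve(exposure, symptoms, form: str = "linear") -> ResilienceScorer:
    return ResilienceScorer(form=form).fit(exposure, symptoms)


def residual_resilience(model: ResilienceScorer, exposure, symptoms) -> np.ndarray:
    return model.resilience(exposure, symptoms)


def compute_all(scored: pd.DataFrame, form: str = "linear") -> pd.DataFrame:
    """Three resilience scores per participant from three normative fits.

    res_c, res_g and res_s are inverse residuals against curves fitted on
    the combined (e_c), general (e_g) and specific (e_s) exposure indices.
    Expects the scored analysis sample (complete records) with P present.
    """
    out = scored.copy()
    p = scored["P"].to_numpy(dtype=float)
    for name, col in (("res_c", "e_c"), ("res_g", "e_g"), ("res_s", "e_s")):
        model = fit_normative_curve(scored[col].to_numpy(), p, form=form)
        out[name] = model.resilience(scored[col].to_numpy(), p)
    return out
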