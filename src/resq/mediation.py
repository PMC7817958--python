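"""Baron-Kenny mediation with asymptotic-normal indirect-effect CIs.

Three covariate-adjusted least-squares fits on the same complete rows:

* total effect:  Y ~ X + covariates        -> c
* action path:   M ~ X + covariates        -> a
* outcome path:  Y ~ X + M + covariates    -> b (on M) and c' (on X)

The indirect effect is a*b with a first-order delta-method ("Sobel")
standard error sqrt(a^2 se_b^2 + b^2 se_a^2) and a normal-theory CI; the
second-order term (+ se_a^2 se_b^2) is available behind a flag. For linear
models on common rows the decomposition c = c' + a*b holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regression import CollinearityError, _check_rank, _fit_ols, expand_terms

__all__ = ["MediationResult", "baron_kenny", "sobel_ci"]


@dataclass
class MediationResult:
    x: str
    m: str
    y: str
    a: float
    se_a: float
    p_a: float
    b: float
    se_b: float
    p_b: float
    c: float
    se_c: float
    p_c: float
    c_prime: float
    se_c_prime: float
    p_c_prime: float
    indirect: float
    se_indirect: float
    ci_low: float
    ci_high: float
    level: float
    n: int
    partial_mediation: bool

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def sobel_ci(
    a: float,
    se_a: float,
    b: float,
    se_b: float,
    level: float = 0.99,
    second_order: bool = False,
) -> tuple[float, float, float]:
    """Delta-method CI for the product of two path coefficients.

    Returns (indirect, lower, upper) with indirect = a*b and
    se = sqrt(a^2 se_b^2 + b^2 se_a^2 [+ se_a^2 se_b^2]).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be nonnegative")
    indirect = a * b
    var = a**2 * se_b**2 + b**2 * se_a**2
    if second_order:
        var += se_a**2 * se_b**2
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return indirect, indirect - z * se, indirect + z * se


def baron_kenny(
    data: pd.DataFrame,
    x: str,
    m: str,
    y: str,
    covariates: list[str] | None = None,
    level: float = 0.99,
    second_order: bool = False,
) -> MediationResult:
    """Covariate-adjusted Baron-Kenny mediation of X on Y through M."""
    covariates = list(covariates or [])
    cols = [x, m, y] + covariates
    sub = data[cols].dropna()
    if sub[x].equals(sub[m]):
        raise CollinearityError(f"mediator {m!r} is identical to {x!r}")
    cov_block = expand_terms(sub, covariates)

    def design(*terms: str) -> pd.DataFrame:
        core = pd.concat([sub[t].astype(float).to_frame(t) for t in terms], axis=1)
        return pd.concat([core, cov_block], axis=1)

    import statsmodels.api as sm

    d_out = design(x, m)
    _check_rank(sm.add_constant(d_out, has_constant="add"))

    total = _fit_ols(sub[y].to_numpy(dtype=float), design(x))
    action = _fit_ols(sub[m].to_numpy(dtype=float), design(x))
    outcome = _fit_ols(sub[y].to_numpy(dtype=float), d_out)

    a, se_a, p_a = (float(action.params[x]), float(action.bse[x]), float(action.pvalues[x]))
    b, se_b, p_b = (float(outcome.params[m]), float(outcome.bse[m]), float(outcome.pvalues[m]))
    c, se_c, p_c = (float(total.params[x]), float(total.bse[x]), float(total.pvalues[x]))
    c_p, se_cp, p_cp = (
        float(outcome.params[x]),
        float(outcome.bse[x]),
        float(outcome.pvalues[x]),
    )
    indirect, lo, hi = sobel_ci(a, se_a, b, se_b, level=level, second_order=second_order)
    alpha = 1.0 - level
    significant_indirect = not (lo <= 0.0 <= hi)
    return MediationResult(
        x=x, m=m, y=y,
        a=a, se_a=se_a, p_a=p_a,
        b=b, se_b=se_b, p_b=p_b,
        c=c, se_c=se_c, p_c=p_c,
        c_prime=c_p, se_c_prime=se_cp, p_c_prime=p_cp,
        indirect=indirect,
        se_indirect=float(np.sqrt(a**2 * se_b**2 + b**2 * se_a**2
                                  + (se_a**2 * se_b**2 if second_order else 0.0))),
        ci_low=lo, ci_high=hi, level=level, n=int(total.nobs),
        partial_mediation=bool(significant_indirect and p_cp < alpha),
    )
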