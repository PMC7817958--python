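"""Subgroup interaction models, per-level LASSO ranks, sign-consistency audit.

For each socio-demographic covariate and each resilience factor, one linear
interaction model RES ~ base covariates + covariate + factor +
factor:covariate is fitted; per-level factor slopes (main effect plus the
level's interaction term, with delta-method SEs from the joint covariance)
populate one row of the subgroup table, and the interaction block is tested
with a likelihood-ratio test at the study-wide two-tailed alpha = 0.01.
Per covariate level, an independent penalized ranking gives the relative
factor strengths and deviance ratio. The audit counts sign flips of a
factor's coefficient across levels and confidence intervals crossing zero
over all (level x factor) cells.

Default level definitions: age 18-30/31-45/46-60/61+; education <13/13-16/
17-20/21+ years; the eight income bands; countries with at least ``min_n``
respondents, the rest pooled as 'Other'; gender male/female (the small
'diverse' category is excluded from subgroup analysis, reducing the sample);
diagnosis yes/no (the 'not_assessed' category likewise excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import FACTORS
from .lasso_rank import LassoFactorRanker
from .regression import _fit_ols, expand_terms

__all__ = [
    "SubgroupTable",
    "InteractionFit",
    "assign_subgroup_levels",
    "interaction_model",
    "subgroup_lasso_ranks",
    "sign_consistency",
    "build_subgroup_table",
    "SUBGROUP_COVARIATES",
]

SUBGROUP_COVARIATES = ("gender", "age_group", "country_group", "income_band",
                       "education_group", "diagnosis")

_EXCLUDED_LEVELS = {"gender": {"diverse"}, "diagnosis": {"not_assessed"}}


def assign_subgroup_levels(participants: pd.DataFrame, min_country_n: int = 500) -> pd.DataFrame:
    """Add the binned subgroup columns used by the table machinery."""
    df = participants.copy()
    age_source = df["age_years"] if "age_years" in df.columns else df["age"]
    age = pd.to_numeric(age_source, errors="coerce")
    df["age_group"] = pd.cut(
        age, bins=[17, 30, 45, 60, np.inf], labels=["18-30", "31-45", "46-60", "61+"]
    ).astype(object)
    edu = pd.to_numeric(df["education_years"], errors="coerce")
    df["education_group"] = pd.cut(
        edu, bins=[-np.inf, 12, 16, 20, np.inf], labels=["<13", "13-16", "17-20", "21+"]
    ).astype(object)
    counts = df["country"].value_counts()
    keep = set(counts[counts >= min_country_n].index) - {"Other"}
    df["country_group"] = np.where(df["country"].isin(keep), df["country"], "Other")
    return df


@dataclass
class InteractionFit:
    """Per-level factor slopes and the interaction-block LR test."""

    factor: str
    covariate: str
    levels: list[str]
    slopes: dict[str, float]
    ses: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    lr: float
    df: int
    p_interaction: float
    n: int
    small_levels: list[str] = field(default_factory=list)


def _prepare_subgroup(data: pd.DataFrame, covariate: str) -> pd.DataFrame:
    sub = data.copy()
    excluded = _EXCLUDED_LEVELS.get(covariate, set())
    if excluded:
        sub = sub[~sub[covariate].isin(excluded)]
    return sub[sub[covariate].notna()]


def interaction_model(
    data: pd.DataFrame,
    outcome: str,
    factor: str,
    covariate: str,
    base_covariates: list[str] | None = None,
    level: float = 0.99,
    min_level_size: int = 30,
) -> InteractionFit:
    """Fit the moderation model and extract per-level factor slopes."""
    base_covariates = [c for c in (base_covariates or []) if c != covariate]
    sub = _prepare_subgroup(data, covariate)
    cols = [outcome, factor, covariate] + base_covariates
    sub = sub[cols].dropna()
    levels = sorted(map(str, sub[covariate].unique()))
    if len(levels) < 2:
        raise ValueError(f"covariate {covariate!r} has fewer than 2 usable levels")
    small = [l for l in levels if (sub[covariate] == l).sum() < min_level_size]

    reference = str(sub[covariate].value_counts().idxmax())
    dummy_levels = [l for l in levels if l != reference]
    y = sub[outcome].to_numpy(dtype=float)
    f = sub[factor].to_numpy(dtype=float)
    base_block = expand_terms(sub, base_covariates)
    cov_dummies = pd.DataFrame(
        {f"{covariate}[{l}]": (sub[covariate].astype(str) == l).astype(float) for l in dummy_levels},
        index=sub.index,
    )
    inter = pd.DataFrame(
        {f"{factor}:{covariate}[{l}]": f * cov_dummies[f"{covariate}[{l}]"] for l in dummy_levels},
        index=sub.index,
    )
    factor_col = pd.DataFrame({factor: f}, index=sub.index)
    full = pd.concat([base_block, cov_dummies, factor_col, inter], axis=1)
    reduced = pd.concat([base_block, cov_dummies, factor_col], axis=1)

    fit_full = _fit_ols(y, full)
    fit_reduced = _fit_ols(y, reduced)
    lr = 2.0 * (fit_full.llf - fit_reduced.llf)
    df_int = len(dummy_levels)
    p_int = float(stats.chi2.sf(lr, df_int))

    cov_params = fit_full.cov_params()
    z = stats.norm.ppf(0.5 + level / 2.0)
    slopes, ses, lo, hi = {}, {}, {}, {}
    for l in levels:
        if l == reference:
            beta = float(fit_full.params[factor])
            var = float(cov_params.loc[factor, factor])
        else:
            term = f"{factor}:{covariate}[{l}]"
            beta = float(fit_full.params[factor] + fit_full.params[term])
            var = float(
                cov_params.loc[factor, factor]
                + cov_params.loc[term, term]
                + 2.0 * cov_params.loc[factor, term]
            )
        se = float(np.sqrt(var))
        slopes[l], ses[l] = beta, se
        lo[l], hi[l] = beta - z * se, beta + z * se

    return InteractionFit(
        factor=factor,
        covariate=covariate,
        levels=levels,
        slopes=slopes,
        ses=ses,
        ci_low=lo,
        ci_high=hi,
        lr=float(lr),
        df=df_int,
        p_interaction=p_int,
        n=len(sub),
        small_levels=small,
    )


def subgroup_lasso_ranks(
    data: pd.DataFrame,
    outcome: str,
    covariate: str,
    factors: list[str] | None = None,
    covariate_terms: list[str] | None = None,
    n_folds: int = 10,
    random_state: int | None = None,
) -> tuple[dict[str, dict[str, int]], dict[str, float], list[str]]:
    """Independent penalized ranking per covariate level.

    Returns (ranks per level, deviance ratio per level, skipped levels).
    Levels smaller than the fold count are skipped with a flag.
    """
    factors = list(factors or FACTORS)
    sub = _prepare_subgroup(data, covariate)
    ranks: dict[str, dict[str, int]] = {}
    deviance: dict[str, float] = {}
    skipped: list[str] = []
    for lvl in sorted(map(str, sub[covariate].unique())):
        chunk = sub[sub[covariate].astype(str) == lvl]
        design_terms = factors + [c for c in (covariate_terms or []) if c != covariate]
        block = pd.concat(
            [expand_terms(chunk, design_terms)], axis=1
        ).dropna()
        yv = chunk.loc[block.index, outcome].to_numpy(dtype=float)
        if len(block) < max(n_folds, 2 * len(factors)):
            skipped.append(lvl)
            continue
        ranker = LassoFactorRanker(n_folds=n_folds, random_state=random_state).fit(block, yv)
        ranks[lvl] = ranker.rank(factors)
        deviance[lvl] = ranker.deviance_ratio_
    return ranks, deviance, skipped


@dataclass
class SubgroupTable:
    """Full grid over subgroup covariates: slopes, CIs, interaction flags,
    per-level ranks and deviance ratios."""

    coefficients: pd.DataFrame  # (covariate, level) x factor
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    interaction_p: pd.DataFrame  # covariate x factor
    ranks: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)
    deviance: dict[str, dict[str, float]] = field(default_factory=dict)
    skipped_levels: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return int(self.coefficients.size)


def sign_consistency(table: SubgroupTable) -> dict[str, int]:
    """Audit counts over all (level x factor) cells.

    Sign flips: per factor, the number of minority-sign coefficients across
    levels (0 when every level agrees), summed over factors. Zero crossings:
    cells whose CI spans zero.
    """
    coefs = table.coefficients
    flips = 0
    for factor in coefs.columns:
        signs = np.sign(coefs[factor].to_numpy())
        nonzero = signs[signs != 0]
        if len(nonzero):
            pos = int((nonzero > 0).sum())
            neg = int((nonzero < 0).sum())
            flips += min(pos, neg)
    crossings = int(((table.ci_low <= 0) & (table.ci_high >= 0)).to_numpy().sum())
    return {
        "sign_flips": int(flips),
        "ci_zero_crossings": crossings,
        "n_cells": table.n_cells,
    }


def build_subgroup_table(
    data: pd.DataFrame,
    outcome: str,
    factors: list[str] | None = None,
    subgroup_covariates: list[str] | None = None,
    base_covariates: list[str] | None = None,
    level: float = 0.99,
    alpha: float = 0.01,
    with_lasso: bool = True,
    n_folds: int = 10,
    random_state: int | None = None,
) -> SubgroupTable:
    """Assemble the full subgroup grid (coefficients, CIs, ranks, audit)."""
    factors = list(factors or FACTORS)
    covs = list(subgroup_covariates or SUBGROUP_COVARIATES)
    coef_rows, lo_rows, hi_rows = {}, {}, {}
    inter_p = pd.DataFrame(index=covs, columns=factors, dtype=float)
    for cov in covs:
        fits = {
            f: interaction_model(
                data, outcome, f, cov, base_covariates=base_covariates, level=level
            )
            for f in factors
        }
        levels = fits[factors[0]].levels
        for lvl in levels:
            key = (cov, lvl)
            coef_rows[key] = {f: fits[f].slopes[lvl] for f in factors}
            lo_rows[key] = {f: fits[f].ci_low[lvl] for f in factors}
            hi_rows[key] = {f: fits[f].ci_high[lvl] for f in factors}
        for f in factors:
            inter_p.loc[cov, f] = fits[f].p_interaction

    index = pd.MultiIndex.from_tuples(coef_rows.keys(), names=["covariate", "level"])
    table = SubgroupTable(
        coefficients=pd.DataFrame(list(coef_rows.values()), index=index)[factors],
        ci_low=pd.DataFrame(list(lo_rows.values()), index=index)[factors],
        ci_high=pd.DataFrame(list(hi_rows.values()), index=index)[factors],
        interaction_p=inter_p,
    )
    if with_lasso:
        for cov in covs:
            ranks, dev, skipped = subgroup_lasso_ranks(
                data, outcome, cov, factors=factors,
                n_folds=n_folds, random_state=random_state,
            )
            table.ranks[cov] = ranks
            table.deviance[cov] = dev
            table.skipped_levels[cov] = skipped
    return table
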