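"""Synthetic survey-cohort generator with known ground truth.

The generator draws nine correlated standardized resilience-factor scores,
injects two structural mediation paths (perceived social support -> positive
appraisal style -> stress recovery), endorses 40 stressor items through a
Gaussian-copula model with a shared per-participant exposure propensity,
rates endorsed items on an ordinal 1-5 severity scale, and produces GHQ-12
item responses by discretizing a continuous additive-linear symptom target.
Missingness is concentrated in the trailing stressor block, and invalid
records exercising every cleaning rule can be appended and are tagged in the
returned ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    DEFECT_CLASSES,
    FACTORS,
    GENERAL_ITEMS,
    SPECIFIC_ITEMS,
    ConfigurationError,
    GeneratorConfig,
    default_config,
)

__all__ = [
    "GroundTruth",
    "generate_cohort",
    "inject_invalid_records",
    "CohortSimulator",
    "gs_col",
    "ss_col",
    "sev_col",
    "GHQ_COLUMNS",
]

# Fixed sub-stream labels: adding a record class never perturbs other draws.
_STREAMS = {
    "covariates": 11,
    "factors": 12,
    "stressors": 13,
    "severities": 14,
    "ghq": 15,
    "missingness": 16,
    "invalid": 17,
}

GHQ_COLUMNS = [f"ghq_{i:02d}" for i in range(1, 13)]

_AGE_BANDS = {"18-30": (18, 30), "31-45": (31, 45), "46-60": (46, 60), "61+": (61, 90)}
_EDU_BANDS = {"<13": (6, 12), "13-16": (13, 16), "17-20": (17, 20), "21+": (21, 30)}


def gs_col(item: str) -> str:
    return f"gs_{item}"


def ss_col(item: str) -> str:
    return f"ss_{item}"


def sev_col(endorse_col: str) -> str:
    return f"{endorse_col}_sev"


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[label]])


@dataclass
class GroundTruth:
    """Generative quantities needed by recovery tests.

    ``frame`` holds per-participant latent factor scores, the true
    severity-weighted exposure sums (before any missingness), their z-score
    composite, and the continuous symptom target. ``injected_defects`` maps
    appended record ids to their defect class.
    """

    factor_weights: dict[str, float]
    mediation_paths: dict[str, float]
    exposure_slope: float
    noise_sd: float
    frame: pd.DataFrame
    injected_defects: dict[str, str] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "factor_weights": self.factor_weights,
            "mediation_paths": self.mediation_paths,
            "exposure_slope": self.exposure_slope,
            "noise_sd": self.noise_sd,
            "injected_defects": self.injected_defects,
            "frame": {c: self.frame[c].tolist() for c in self.frame.columns},
        }


def _sample_categorical(
    rng: np.random.Generator, dist: dict[str, float], n: int
) -> np.ndarray:
    levels = list(dist.keys())
    probs = np.asarray([dist[k] for k in levels], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(levels, size=n, p=probs)


def _sample_covariates(cfg: GeneratorConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    out: dict[str, np.ndarray] = {}
    dists = cfg.covariate_distributions
    out["gender"] = _sample_categorical(rng, dists["gender"], n)
    age_band = _sample_categorical(rng, dists["age_band"], n)
    ages = np.empty(n, dtype=int)
    for band, (lo, hi) in _AGE_BANDS.items():
        mask = age_band == band
        ages[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    # age is stored as free text so invalid entries are representable
    out["age"] = ages.astype(str)
    out["country"] = _sample_categorical(rng, dists["country"], n)
    out["income_band"] = _sample_categorical(rng, dists["income_band"], n)
    edu_band = _sample_categorical(rng, dists["education_band"], n)
    years = np.empty(n, dtype=float)
    for band, (lo, hi) in _EDU_BANDS.items():
        mask = edu_band == band
        years[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    out["education_years"] = years
    out["diagnosis"] = _sample_categorical(rng, dists["diagnosis"], n)
    out["employment"] = _sample_categorical(rng, dists["employment"], n)
    df = pd.DataFrame(out)
    df["income_scale"] = "current"
    return df


def _draw_factors(cfg: GeneratorConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    try:
        chol = np.linalg.cholesky(cfg.factor_correlation)
    except np.linalg.LinAlgError:
        raise ConfigurationError("factor_correlation is not positive-definite") from None
    base = rng.standard_normal((n, len(FACTORS))) @ chol.T
    f = pd.DataFrame(base, columns=list(FACTORS))
    a1 = cfg.mediation_paths.get("a1", 0.0)
    a2 = cfg.mediation_paths.get("a2", 0.0)
    # structural overwrite keeps unit variance when disturbances are
    # independent of the upstream variable (default base correlations)
    f["pas"] = a1 * f["pss"] + np.sqrt(max(0.0, 1 - a1**2)) * f["pas"]
    f["rec"] = a2 * f["pas"] + np.sqrt(max(0.0, 1 - a2**2)) * f["rec"]
    return f


def _endorse_and_rate(
    cfg: GeneratorConfig,
    n: int,
    rng_endorse: np.random.Generator,
    rng_sev: np.random.Generator,
) -> pd.DataFrame:
    rho = cfg.shared_propensity
    u = rng_endorse.standard_normal(n)
    cols: dict[str, np.ndarray] = {}
    for item in GENERAL_ITEMS + SPECIFIC_ITEMS:
        col = gs_col(item) if item in GENERAL_ITEMS else ss_col(item)
        p = cfg.stressor_prevalences[item]
        z = rho * u + np.sqrt(max(0.0, 1 - rho**2)) * rng_endorse.standard_normal(n)
        endorsed = (z < stats.norm.ppf(p)).astype(float)
        sev = np.full(n, np.nan)
        k = int(endorsed.sum())
        if k:
            dist = np.asarray(cfg.severity_distribution[item], dtype=float)
            sev[endorsed == 1] = rng_sev.choice([1, 2, 3, 4, 5], size=k, p=dist / dist.sum())
        cols[col] = endorsed
        cols[sev_col(col)] = sev
    return pd.DataFrame(cols)


def _weighted_sum(stressors: pd.DataFrame, items: tuple[str, ...], prefix) -> np.ndarray:
    total = np.zeros(len(stressors))
    for item in items:
        col = prefix(item)
        sev = stressors[sev_col(col)].to_numpy()
        endorsed = stressors[col].to_numpy()
        total += np.where(endorsed == 1, np.nan_to_num(sev), 0.0)
    return total


def _discretize_ghq(target: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Spread a continuous 0-36 target across 12 items of 0-3.

    Largest-remainder allocation on equal quotas: every item gets
    floor(T/12); the integer remainder is distributed one unit each to a
    seeded random subset of items (quota remainders are tied, so the
    tie-break is random but reproducible).
    """
    t = np.clip(np.rint(np.clip(target, 0.0, 36.0)), 0, 36).astype(int)
    n = len(t)
    base = t // 12
    rem = t % 12
    items = np.repeat(base[:, None], 12, axis=1)
    # one random permutation per participant; first rem[i] slots get +1
    order = np.argsort(rng.random((n, 12)), axis=1)
    bump = order < rem[:, None]
    items = items + bump.astype(int)
    return pd.DataFrame(items, columns=GHQ_COLUMNS)


def _covariate_shift(cfg: GeneratorConfig, cov: pd.DataFrame) -> np.ndarray:
    shift = np.zeros(len(cov))
    for col, levels in cfg.covariate_effects.items():
        for level, delta in levels.items():
            shift += np.where(cov[col].to_numpy() == level, delta, 0.0)
    return shift


def _effective_weights(cfg: GeneratorConfig, cov: pd.DataFrame) -> pd.DataFrame:
    """Per-participant factor weights after subgroup weight modifiers."""
    n = len(cov)
    w = pd.DataFrame(
        {k: np.full(n, cfg.factor_weights.get(k, 0.0)) for k in FACTORS}
    )
    age = pd.to_numeric(cov["age"], errors="coerce")
    for covariate, level, factor, mult in cfg.weight_modifiers:
        if covariate == "age_band":
            lo, hi = _AGE_BANDS[level]
            mask = (age >= lo) & (age <= hi)
        elif covariate == "education_band":
            lo, hi = _EDU_BANDS[level]
            mask = (cov["education_years"] >= lo) & (cov["education_years"] <= hi)
        else:
            mask = cov[covariate] == level
        w.loc[mask.to_numpy(), factor] *= mult
    return w


def generate_cohort(config: GeneratorConfig | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one raw response set plus its ground truth.

    Fully reproducible from ``config.seed``; the record count is
    ``n_participants`` plus the injected invalid records.
    """
    cfg = config if config is not None else default_config()
    cfg.validate()
    n, seed = cfg.n_participants, cfg.seed

    cov = _sample_covariates(cfg, n, _rng(seed, "covariates"))
    factors = _draw_factors(cfg, n, _rng(seed, "factors"))
    stressors = _endorse_and_rate(cfg, n, _rng(seed, "stressors"), _rng(seed, "severities"))

    e_g = _weighted_sum(stressors, GENERAL_ITEMS, gs_col)
    e_s = _weighted_sum(stressors, SPECIFIC_ITEMS, ss_col)

    def _z(x: np.ndarray) -> np.ndarray:
        sd = x.std(ddof=1)
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    e_true = 0.5 * (_z(e_g) + _z(e_s))

    rng_ghq = _rng(seed, "ghq")
    weights = _effective_weights(cfg, cov)
    factor_term = (weights.to_numpy() * factors[list(FACTORS)].to_numpy()).sum(axis=1)
    p_cont = (
        cfg.symptom_intercept
        + cfg.exposure_slope * e_true
        - factor_term
        + _covariate_shift(cfg, cov)
        + rng_ghq.normal(0.0, cfg.noise_sd, size=n)
    )
    ghq = _discretize_ghq(p_cont, rng_ghq)

    records = pd.concat([cov, factors, ghq, stressors], axis=1)
    records.insert(0, "participant_id", [f"P{i:06d}" for i in range(n)])
    records["free_text"] = ""  # optional question, never required

    # missingness concentrated in the trailing stressor block
    rng_miss = _rng(seed, "missingness")
    blank = rng_miss.random(n) < cfg.missingness
    stressor_cols = [c for c in records.columns if c.startswith(("gs_", "ss_"))]
    records.loc[blank, stressor_cols] = np.nan

    truth_frame = factors.copy()
    truth_frame["e_g_true"] = e_g
    truth_frame["e_s_true"] = e_s
    truth_frame["e_c_true"] = e_true
    truth_frame["p_cont"] = p_cont
    truth_frame.insert(0, "participant_id", records["participant_id"].to_numpy())

    truth = GroundTruth(
        factor_weights=dict(cfg.factor_weights),
        mediation_paths=dict(cfg.mediation_paths),
        exposure_slope=cfg.exposure_slope,
        noise_sd=cfg.noise_sd,
        frame=truth_frame,
    )

    if any(cfg.invalid_counts.values()):
        records, tags = inject_invalid_records(records, cfg.invalid_counts, seed)
        truth.injected_defects = tags

    return records, truth


def inject_invalid_records(
    records: pd.DataFrame, invalid_counts: dict[str, int], seed: int
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Append tagged defective records, one batch per defect class.

    Returns the augmented response set and a mapping from appended record
    id to its defect class. Unknown class names raise with the valid list.
    """
    for cls, count in invalid_counts.items():
        if cls not in DEFECT_CLASSES:
            raise ValueError(
                f"unknown defect class {cls!r}; valid classes: {', '.join(DEFECT_CLASSES)}"
            )
        if count < 0:
            raise ValueError("defect counts must be nonnegative")
    total = sum(invalid_counts.values())
    if total == 0:
        return records, {}
    if records.empty:
        raise ValueError("cannot derive invalid records from an empty response set")

    rng = _rng(seed, "invalid")
    donors = records.iloc[rng.integers(0, len(records), size=total)].copy()
    donors = donors.reset_index(drop=True)
    tags: dict[str, str] = {}
    row = 0
    bad_ages = ["abc", "??", "one hundred", "-4", "999"]
    for cls in DEFECT_CLASSES:  # fixed order => reproducible ids per class
        for _ in range(invalid_counts.get(cls, 0)):
            rid = f"X{row:06d}"
            donors.loc[row, "participant_id"] = rid
            if cls == "invalid_age":
                donors.loc[row, "age"] = bad_ages[row % len(bad_ages)]
            elif cls == "underage":
                donors.loc[row, "age"] = str(int(rng.integers(8, 18)))
            elif cls == "missing_initial_sociodemo":
                donors.loc[row, ["age", "gender", "country"]] = np.nan
            elif cls == "prefinal_income":
                donors.loc[row, "income_scale"] = "prefinal"
            elif cls == "missing_followup_sociodemo":
                donors.loc[row, ["education_years", "employment"]] = np.nan
            tags[rid] = cls
            row += 1
    out = pd.concat([records, donors], ignore_index=True)
    return out, tags


class CohortSimulator:
    """Thin object wrapper pairing a config with its generation call."""

    def __init__(self, config: GeneratorConfig | None = None):
        self.config = config if config is not None else default_config()

    def generate(self) -> tuple[pd.DataFrame, GroundTruth]:
        return generate_cohort(self.config)
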