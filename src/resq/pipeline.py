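"""End-to-end orchestration: simulate/load -> clean -> score -> resilience
-> screen -> factor tests -> mediation -> penalized ranking -> subgroups.

Every stage persists a plain-text intermediate (CSV) and the final report is
a single JSON bundle with a provenance block (config hash, seed, package
version), so a rerun with identical configuration reproduces the outputs
byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cleaning import clean
from .config import FACTORS, GENERAL_ITEMS, SPECIFIC_ITEMS, GeneratorConfig, default_config
from .lasso_rank import LassoFactorRanker
from .mediation import baron_kenny
from .regression import expand_terms, screen_covariates, test_factor
from .resilience import compute_all
from .scoring import score_cohort
from .simulate import GHQ_COLUMNS, generate_cohort, gs_col, sev_col, ss_col
from .subgroup import SUBGROUP_COVARIATES, assign_subgroup_levels, build_subgroup_table, sign_consistency

__all__ = ["PipelineConfig", "run_pipeline", "describe_stressors", "PipelineError"]

log = logging.getLogger("resq")

DEFAULT_COVARIATES = [
    "gender", "age_years", "country", "income_band",
    "education_years", "diagnosis", "employment",
]
DEFAULT_MEDIATIONS = [("pss", "pas", "res_c"), ("pas", "rec", "res_c")]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending item."""


@dataclass
class PipelineConfig:
    """Paths, rosters and tuning for one pipeline run."""

    generator: GeneratorConfig = field(default_factory=default_config)
    input_csv: str | None = None  # if set, skip simulation and load this table
    outdir: str = "resq_out"
    factors: list[str] = field(default_factory=lambda: list(FACTORS))
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    mediations: list[tuple[str, str, str]] = field(
        default_factory=lambda: list(DEFAULT_MEDIATIONS)
    )
    subgroup_covariates: list[str] = field(default_factory=lambda: list(SUBGROUP_COVARIATES))
    screening_threshold: float = 0.2
    alpha: float = 0.01
    ci_level: float = 0.99
    lasso_folds: int = 10
    stability_runs: int = 50
    subgroup_lasso: bool = True
    resilience_form: str = "linear"
    seed: int = 0

    def hash(self) -> str:
        import hashlib

        payload = {
            "generator": self.generator.hash(),
            "input_csv": self.input_csv,
            "factors": self.factors,
            "covariates": self.covariates,
            "mediations": [list(m) for m in self.mediations],
            "subgroup_covariates": self.subgroup_covariates,
            "screening_threshold": self.screening_threshold,
            "alpha": self.alpha,
            "ci_level": self.ci_level,
            "lasso_folds": self.lasso_folds,
            "stability_runs": self.stability_runs,
            "subgroup_lasso": self.subgroup_lasso,
            "resilience_form": self.resilience_form,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _required_columns() -> list[str]:
    cols = ["participant_id", "age", "gender", "country", "income_band",
            "income_scale", "education_years", "diagnosis", "employment"]
    cols += list(FACTORS) + GHQ_COLUMNS
    for item in GENERAL_ITEMS:
        cols += [gs_col(item), sev_col(gs_col(item))]
    for item in SPECIFIC_ITEMS:
        cols += [ss_col(item), sev_col(ss_col(item))]
    return cols


def _schema_check(cohort: pd.DataFrame, cfg: PipelineConfig) -> None:
    missing = [c for c in _required_columns() if c not in cohort.columns]
    missing += [f for f in cfg.factors if f not in cohort.columns]
    if missing:
        raise PipelineError(
            f"schema check failed before analysis: missing columns {sorted(set(missing))}"
        )


def describe_stressors(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-item endorsement percentage and mean severity among endorsers,
    sorted by frequency within domain. Items endorsed by nobody report a
    missing severity."""
    rows = []
    for domain, items, prefix in (
        ("general", GENERAL_ITEMS, gs_col),
        ("specific", SPECIFIC_ITEMS, ss_col),
    ):
        for item in items:
            col = prefix(item)
            e = scored[col]
            answered = e.notna()
            freq = float((e[answered] == 1).mean() * 100) if answered.any() else np.nan
            sev = scored.loc[e == 1, sev_col(col)]
            rows.append(
                {
                    "domain": domain,
                    "item": item,
                    "frequency_pct": freq,
                    "mean_severity": float(sev.mean()) if len(sev) else np.nan,
                    "n_endorsed": int((e == 1).sum()),
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["domain", "frequency_pct"], ascending=[True, False]
    ).reset_index(drop=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns (and persists) the report bundle."""
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- simulate or load ---------------------------------------------
    if cfg.input_csv:
        cohort = pd.read_csv(cfg.input_csv, dtype={"age": str})
        truth = None
    else:
        gen = cfg.generator
        cohort, truth = generate_cohort(gen)
    _schema_check(cohort, cfg)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    log.info("simulate: %d records", len(cohort))

    # ---- clean ---------------------------------------------------------
    participants, report = clean(cohort)
    participants.to_csv(outdir / "participants.csv", index=False)
    (outdir / "cleaning.json").write_text(json.dumps(report.to_dict(), indent=2))
    log.info("clean: %d in, %d valid (%d complete)",
             report.n_registered, report.n_valid, report.n_complete)

    complete = participants[participants["complete"]].reset_index(drop=True)
    if len(complete) < 10:
        raise PipelineError("scoring: fewer than 10 complete participants")

    # ---- score + resilience --------------------------------------------
    scored = score_cohort(complete)
    res = compute_all(scored, form=cfg.resilience_form)
    res = assign_subgroup_levels(res)
    res.to_csv(outdir / "res.csv", index=False)
    stressor_table = describe_stressors(scored)
    stressor_table.to_csv(outdir / "stressors.csv", index=False)

    # ---- covariate screening -------------------------------------------
    screening = screen_covariates(
        res, "res_c", cfg.covariates, threshold=cfg.screening_threshold
    )
    retained = [c for c in cfg.covariates if screening.loc[c, "retained"]]
    log.info("screening: retained %s", retained)

    # ---- directed hypothesis tests -------------------------------------
    fits = {}
    for factor in cfg.factors:
        fits[factor] = test_factor(
            res, "res_c", factor, retained, level=cfg.ci_level
        ).to_dict()

    # ---- mediation -------------------------------------------------------
    mediations = {}
    for x, m, y in cfg.mediations:
        key = f"{x}->{m}->{y}"
        mediations[key] = baron_kenny(
            res, x, m, y, covariates=retained, level=cfg.ci_level
        ).to_dict()

    # ---- penalized ranking ----------------------------------------------
    design = pd.concat(
        [res[cfg.factors].astype(float), expand_terms(res, retained)], axis=1
    )
    mask = design.notna().all(axis=1) & res["res_c"].notna()
    ranker = LassoFactorRanker(
        n_folds=cfg.lasso_folds, random_state=cfg.seed
    ).fit(design[mask], res.loc[mask, "res_c"].to_numpy())
    lasso_result = ranker.result(factors=cfg.factors)
    if cfg.stability_runs > 0:
        lasso_result.selection_frequency = ranker.stability(runs=cfg.stability_runs)
    lasso_result.coef_path.to_csv(outdir / "lasso_path.csv")

    # ---- subgroups -------------------------------------------------------
    table = build_subgroup_table(
        res, "res_c",
        factors=cfg.factors,
        subgroup_covariates=cfg.subgroup_covariates,
        base_covariates=retained,
        level=cfg.ci_level,
        alpha=cfg.alpha,
        with_lasso=cfg.subgroup_lasso,
        n_folds=cfg.lasso_folds,
        random_state=cfg.seed,
    )
    audit = sign_consistency(table)
    table.coefficients.to_csv(outdir / "subgroup_coefficients.csv")

    report_bundle = {
        "provenance": {
            "config_hash": cfg.hash(),
            "seed": cfg.seed,
            "version": __version__,
        },
        "cleaning": report.to_dict(),
        "stressors": stressor_table.to_dict(orient="records"),
        "screening": screening.reset_index().to_dict(orient="records"),
        "retained_covariates": retained,
        "factor_fits": fits,
        "bonferroni_threshold": cfg.alpha / len(cfg.factors),
        "mediation": mediations,
        "lasso": {
            "lambda_min": lasso_result.lambda_min,
            "lambda_opt": lasso_result.lambda_opt,
            "coefficients": lasso_result.coefficients,
            "deviance_ratio": lasso_result.deviance_ratio,
            "selection_frequency": lasso_result.selection_frequency,
            "factor_ranks": lasso_result.factor_ranks,
        },
        "subgroups": {
            "coefficients": {
                f"{c}|{l}": {k: float(v) for k, v in row.items()}
                for (c, l), row in table.coefficients.iterrows()
            },
            "interaction_p": {
                c: {f: float(table.interaction_p.loc[c, f]) for f in table.interaction_p.columns}
                for c in table.interaction_p.index
            },
            "ranks": table.ranks,
            "deviance": table.deviance,
            "skipped_levels": table.skipped_levels,
            "audit": audit,
        },
    }
    bundle = _jsonable(report_bundle)
    (outdir / "report.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
    return bundle
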