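"""Symptom totals and severity-weighted stressor-exposure indices.

The 12-item GHQ is scored 0-3 per item (Likert scoring; totals range 0-36).
Exposure to general (E_G, 11 classes) and crisis-specific (E_S, 29 items)
stressors is the sum of severity ratings over endorsed items; the combined
index E_C averages the two z-normalized sums, with z-scores computed on the
analysis sample (n-1 denominator).
"""

from __future__ import annotations

from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .config import GENERAL_ITEMS, SPECIFIC_ITEMS
from .simulate import GHQ_COLUMNS, gs_col, sev_col, ss_col

__all__ = [
    "ScoringError",
    "score_ghq12",
    "exposure_sum",
    "combine_exposure",
    "score_cohort",
]

GHQ_MIN, GHQ_MAX = 0, 3


class ScoringError(ValueError):
    """A response vector violates the instrument's coding."""


def score_ghq12(items: Iterable[float]) -> int:
    """Plain sum of 12 items each coded 0-3; total in 0..36."""
    values = list(items)
    if len(values) != 12:
        raise ScoringError(f"expected 12 GHQ items, got {len(values)}")
    total = 0
    for i, v in enumerate(values):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ScoringError(f"GHQ item {i + 1} is missing")
        if v not in (0, 1, 2, 3):
            raise ScoringError(f"GHQ item {i + 1} outside 0-3: {v!r}")
        total += int(v)
    return total


_DOMAIN_SIZE = {"general": len(GENERAL_ITEMS), "specific": len(SPECIFIC_ITEMS)}


def exposure_sum(
    endorsements: Iterable[float],
    severities: Iterable[float],
    domain: Literal["general", "specific"],
    mode: Literal["strict", "lenient"] = "strict",
) -> float:
    """Severity-weighted sum count over one participant's stressor list.

    Unendorsed items contribute 0. An endorsed item lacking a severity is an
    error in strict mode; in lenient mode it is imputed at the scale
    midpoint 3.
    """
    e = np.asarray(list(endorsements), dtype=float)
    s = np.asarray(list(severities), dtype=float)
    expected = _DOMAIN_SIZE.get(domain)
    if expected is None:
        raise ScoringError(f"unknown stressor domain {domain!r}")
    if e.shape != (expected,) or s.shape != (expected,):
        raise ScoringError(
            f"{domain} domain has {expected} items; got "
            f"{e.shape[0]} endorsements / {s.shape[0]} severities"
        )
    endorsed = e == 1
    missing_sev = endorsed & np.isnan(s)
    if missing_sev.any():
        if mode == "strict":
            idx = int(np.flatnonzero(missing_sev)[0])
            raise ScoringError(
                f"endorsed {domain} item {idx} has no severity rating"
            )
        s = np.where(missing_sev, 3.0, s)
    valid_sev = endorsed & ~np.isnan(s) & ((s < 1) | (s > 5))
    if valid_sev.any():
        idx = int(np.flatnonzero(valid_sev)[0])
        raise ScoringError(f"severity of {domain} item {idx} outside 1-5")
    return float(np.where(endorsed, np.nan_to_num(s), 0.0).sum())


def combine_exposure(e_g: Iterable[float], e_s: Iterable[float]) -> pd.DataFrame:
    """z-normalize both exposure sums on this sample and average them.

    z-scores use the sample mean and n-1 SD; E_C = (z_G + z_S) / 2.
    Raises on fewer than two participants or a zero-variance sum.
    """
    g = np.asarray(list(e_g), dtype=float)
    s = np.asarray(list(e_s), dtype=float)
    if g.shape != s.shape or g.ndim != 1:
        raise ScoringError("e_g and e_s must be equal-length vectors")
    if len(g) < 2:
        raise ScoringError("need at least two participants to z-normalize")
    out = {}
    for name, x in (("g", g), ("s", s)):
        sd = x.std(ddof=1)
        if sd == 0:
            raise ScoringError(f"e_{name} has zero variance; z-score undefined")
        out[f"z_{name}"] = (x - x.mean()) / sd
    return pd.DataFrame(
        {
            "e_g": g,
            "e_s": s,
            "z_g": out["z_g"],
            "z_s": out["z_s"],
            "e_c": 0.5 * (out["z_g"] + out["z_s"]),
        }
    )


def score_cohort(participants: pd.DataFrame, mode: str = "strict") -> pd.DataFrame:
    """Append P, e_g, e_s, z_g, z_s and e_c columns to complete participants.

    z-normalization is computed over the rows passed in, which should be the
    analysis sample (complete records).
    """
    df = participants.copy()
    p = df[GHQ_COLUMNS].to_numpy()
    if np.isnan(p).any() or ((p < GHQ_MIN) | (p > GHQ_MAX)).any():
        bad = int(np.flatnonzero(np.isnan(p).any(axis=1) | ((p < 0) | (p > 3)).any(axis=1))[0])
        raise ScoringError(f"row {bad} has invalid or missing GHQ items")
    df["P"] = p.sum(axis=1).astype(int)

    def _sums(items, prefix) -> np.ndarray:
        total = np.zeros(len(df))
        for item in items:
            col = prefix(item)
            e = df[col].to_numpy(dtype=float)
            s = df[sev_col(col)].to_numpy(dtype=float)
            endorsed = e == 1
            miss = endorsed & np.isnan(s)
            if miss.any():
                if mode == "strict":
                    raise ScoringError(
                        f"endorsed item {col} missing severity in {int(miss.sum())} rows"
                    )
                s = np.where(miss, 3.0, s)
            total += np.where(endorsed, np.nan_to_num(s), 0.0)
        return total

    e_g = _sums(GENERAL_ITEMS, gs_col)
    e_s = _sums(SPECIFIC_ITEMS, ss_col)
    combined = combine_exposure(e_g, e_s)
    for col in combined.columns:
        df[col] = combined[col].to_numpy()
    return df
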