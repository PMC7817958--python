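"""Record-removal rules and complete/incomplete classification.

Five removal rules are applied in a fixed order, and a record failing
several rules is attributed to the first one it matches, so per-rule counts
partition the removed set:

1. ``invalid_age`` — an age answer was given but is not a number in [0, 120]
2. ``underage`` — numeric age below 18
3. ``missing_initial_sociodemo`` — age, gender or country unanswered
   (survey terminated before the initial socio-demographic questions)
4. ``prefinal_income`` — household income reported on the superseded scale
5. ``missing_followup_sociodemo`` — education years or employment unanswered

Surviving records are classified complete iff every GHQ-12 item and every
stressor endorsement is answered and every endorsed stressor has a severity
rating. Optional free-text answers never affect the classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEFECT_CLASSES, GENERAL_ITEMS, SPECIFIC_ITEMS
from .simulate import GHQ_COLUMNS, gs_col, sev_col, ss_col

__all__ = ["CleaningReport", "clean", "classify_completeness", "RULE_ORDER"]

RULE_ORDER: tuple[str, ...] = DEFECT_CLASSES  # applied in this fixed order


@dataclass
class CleaningReport:
    """Counts and per-record dispositions of one cleaning pass.

    Invariants: ``n_registered == n_removed + n_valid`` and
    ``n_valid == n_incomplete + n_complete``; dispositions partition the
    input (each record carries either the first rule it triggered, or
    'complete'/'incomplete').
    """

    n_registered: int
    n_removed: int
    removed_by_rule: dict[str, int]
    n_valid: int
    n_incomplete: int
    n_complete: int
    dispositions: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    @classmethod
    def from_counts(
        cls, n_registered: int, n_removed: int, n_incomplete: int
    ) -> "CleaningReport":
        """Derive the remaining tallies from three headline counts."""
        n_valid = n_registered - n_removed
        return cls(
            n_registered=n_registered,
            n_removed=n_removed,
            removed_by_rule={},
            n_valid=n_valid,
            n_incomplete=n_incomplete,
            n_complete=n_valid - n_incomplete,
        )

    @property
    def incomplete_fraction(self) -> float:
        return self.n_incomplete / self.n_valid if self.n_valid else 0.0

    def validate(self) -> None:
        assert self.n_registered == self.n_removed + self.n_valid
        assert self.n_valid == self.n_incomplete + self.n_complete
        if self.removed_by_rule:
            assert sum(self.removed_by_rule.values()) == self.n_removed

    def to_dict(self) -> dict:
        return {
            "n_registered": self.n_registered,
            "n_removed": self.n_removed,
            "removed_by_rule": dict(self.removed_by_rule),
            "n_valid": self.n_valid,
            "n_incomplete": self.n_incomplete,
            "n_complete": self.n_complete,
            "incomplete_fraction": self.incomplete_fraction,
        }


def _is_missing(values: pd.Series) -> pd.Series:
    s = values.isna()
    if values.dtype == object:
        s = s | (values.astype(str).str.strip() == "")
    return s


def _rule_masks(raw: pd.DataFrame) -> dict[str, pd.Series]:
    age_raw = raw["age"]
    age_missing = _is_missing(age_raw)
    age_num = pd.to_numeric(age_raw, errors="coerce")
    answered_unparseable = ~age_missing & age_num.isna()
    out_of_range = age_num.notna() & ((age_num < 0) | (age_num > 120))
    return {
        "invalid_age": answered_unparseable | out_of_range,
        "underage": age_num.notna() & (age_num >= 0) & (age_num < 18),
        "missing_initial_sociodemo": (
            age_missing | _is_missing(raw["gender"]) | _is_missing(raw["country"])
        ),
        "prefinal_income": raw["income_scale"] == "prefinal",
        "missing_followup_sociodemo": (
            _is_missing(raw["education_years"]) | _is_missing(raw["employment"])
        ),
    }


def classify_completeness(record: pd.Series) -> str:
    """Return 'complete' or 'incomplete' for a record that survived cleaning.

    Complete means: all 12 GHQ items answered, all 40 stressor endorsements
    answered, and a severity present for every endorsed item. Optional
    free-text fields are ignored.
    """
    for col in GHQ_COLUMNS:
        if pd.isna(record[col]):
            return "incomplete"
    for item in GENERAL_ITEMS + SPECIFIC_ITEMS:
        col = gs_col(item) if item in GENERAL_ITEMS else ss_col(item)
        e = record[col]
        if pd.isna(e):
            return "incomplete"
        if e == 1 and pd.isna(record[sev_col(col)]):
            return "incomplete"
    return "complete"


def _completeness_mask(df: pd.DataFrame) -> pd.Series:
    ok = pd.Series(True, index=df.index)
    for col in GHQ_COLUMNS:
        ok &= df[col].notna()
    for item in GENERAL_ITEMS + SPECIFIC_ITEMS:
        col = gs_col(item) if item in GENERAL_ITEMS else ss_col(item)
        ok &= df[col].notna()
        ok &= ~((df[col] == 1) & df[sev_col(col)].isna())
    return ok


def clean(raw: pd.DataFrame) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the removal rules; classify survivors' completeness.

    Returns the valid participants (with a parsed numeric ``age_years``
    column and a boolean ``complete`` column) plus the reconciled report.
    A malformed field is a removal reason, never an exception.
    """
    n_registered = len(raw)
    if n_registered == 0:
        report = CleaningReport(0, 0, {r: 0 for r in RULE_ORDER}, 0, 0, 0)
        return raw.copy(), report

    masks = _rule_masks(raw)
    disposition = pd.Series("valid", index=raw.index, dtype=object)
    removed_by_rule: dict[str, int] = {}
    unassigned = pd.Series(True, index=raw.index)
    for rule in RULE_ORDER:
        hit = masks[rule] & unassigned
        removed_by_rule[rule] = int(hit.sum())
        disposition[hit] = rule
        unassigned &= ~hit

    valid = raw[unassigned].copy()
    valid["age_years"] = pd.to_numeric(valid["age"], errors="coerce")
    complete = _completeness_mask(valid)
    valid["complete"] = complete
    disposition[valid.index] = np.where(complete, "complete", "incomplete")

    n_removed = int(sum(removed_by_rule.values()))
    report = CleaningReport(
        n_registered=n_registered,
        n_removed=n_removed,
        removed_by_rule=removed_by_rule,
        n_valid=len(valid),
        n_incomplete=int((~complete).sum()),
        n_complete=int(complete.sum()),
        dispositions=disposition,
    )
    report.validate()
    return valid.reset_index(drop=True), report
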