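"""Blood-pressure and BMI categorisation, tertile risk cutoffs and flags.

Blood pressure follows JNC7: normal < 120/80, prehypertension 120–139 or
80–89, hypertension ≥ 140 or ≥ 90, combined by the more severe of the two
bands; anyone on antihypertensive treatment is classified hypertensive
regardless of measured pressure.

Risk cutoffs for the emergent indices are tertile boundaries of the
analysis cohort itself: for BRI, wBMI and PI values at or above the first
tertile boundary (33.33rd percentile) are the risk category; for the other
indices it is the second boundary (66.67th percentile). PMI uses the fixed
threshold > 1.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .indices import EMERGENT, percentile


class BPCategory(str, Enum):
    NORMOTENSIVE = "normotensive"
    PREHYPERTENSION = "prehypertension"
    HYPERTENSION = "hypertension"


class BMICategory(str, Enum):
    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESITY = "obesity"


SECOND_TERTILE = "second_tertile"   # cutoff at the 33.33rd percentile
THIRD_TERTILE = "third_tertile"     # cutoff at the 66.67th percentile
FIXED_GT_1 = "fixed_gt_1"           # constant threshold 1, strict >

#: which rule produces each emergent index's risk cutoff
TERTILE_RULES: dict[str, str] = {
    "BRI": SECOND_TERTILE, "WBMI": SECOND_TERTILE, "PI": SECOND_TERTILE,
    "WHHR": THIRD_TERTILE, "AWI": THIRD_TERTILE, "HWrI": THIRD_TERTILE,
    "WWrI": THIRD_TERTILE, "WHT2": THIRD_TERTILE, "WHT3": THIRD_TERTILE,
    "BAI": THIRD_TERTILE, "ABSI": THIRD_TERTILE, "CI": THIRD_TERTILE,
    "BFDI": THIRD_TERTILE, "AVI": THIRD_TERTILE,
    "PMI": FIXED_GT_1,
}
# Every emergent index except H3W3 carries a risk rule: H3W3 falls with
# adiposity and has no published upper-tertile cutoff, so it is computed
# and described but never flagged.
FLAGGED = tuple(i for i in EMERGENT if i in TERTILE_RULES)
assert set(TERTILE_RULES) == set(EMERGENT) - {"H3W3"}


def classify_bp(sbp: float, dbp: float, on_treatment: bool = False) -> BPCategory:
    """JNC7 category for one participant (max-severity rule over SBP/DBP)."""
    if on_treatment:
        return BPCategory.HYPERTENSION
    if sbp >= 140 or dbp >= 90:
        return BPCategory.HYPERTENSION
    if sbp >= 120 or dbp >= 80:
        return BPCategory.PREHYPERTENSION
    return BPCategory.NORMOTENSIVE


def classify_bp_frame(frame: pd.DataFrame) -> pd.Series:
    """Vectorised JNC7 classification over a cohort frame."""
    sbp = frame["sbp_mmhg"].to_numpy(dtype=float)
    dbp = frame["dbp_mmhg"].to_numpy(dtype=float)
    treated = frame["antihypertensive"].to_numpy().astype(bool)
    cat = np.where(
        treated | (sbp >= 140) | (dbp >= 90), BPCategory.HYPERTENSION.value,
        np.where((sbp >= 120) | (dbp >= 80), BPCategory.PREHYPERTENSION.value,
                 BPCategory.NORMOTENSIVE.value),
    )
    return pd.Series(cat, index=frame.index, name="bp_category")


def classify_bmi(bmi: float) -> BMICategory:
    """WHO adult BMI bands; boundaries 18.5, 25 and 30 go to the higher class."""
    if bmi <= 0:
        raise ValueError(f"bmi must be positive, got {bmi}")
    if bmi < 18.5:
        return BMICategory.UNDERWEIGHT
    if bmi < 25.0:
        return BMICategory.NORMAL
    if bmi < 30.0:
        return BMICategory.OVERWEIGHT
    return BMICategory.OBESITY


@dataclass
class RiskCutoffSet:
    """Per-index risk cutoff and the rule that produced it."""

    cutoffs: dict[str, float]
    rules: dict[str, str]
    fingerprint: str = ""   # derivation-cohort fingerprint (n + value hash)

    def __getitem__(self, index_id: str) -> float:
        return self.cutoffs[index_id]

    def to_dict(self) -> dict:
        return {
            "cutoffs": self.cutoffs, "rules": self.rules,
            "fingerprint": self.fingerprint,
        }


def tertile_cutoff(values, rule: str) -> float:
    """Cutoff for one value vector under one rule (rank-interpolated)."""
    v = np.asarray(values, dtype=float)
    if rule == FIXED_GT_1:
        return 1.0
    if len(v) < 3:
        raise ValueError(f"need >= 3 values for a tertile cutoff, got {len(v)}")
    p = 1.0 / 3.0 if rule == SECOND_TERTILE else 2.0 / 3.0
    return percentile(v, p)


def derive_cutoffs(
    panels: pd.DataFrame, rules: Optional[Mapping[str, str]] = None
) -> RiskCutoffSet:
    """Derive the risk-cutoff set from a cohort's index panels.

    ``panels`` has one row per participant and one column per index.
    ``rules`` defaults to the emergent-index rule table; extra columns
    (e.g. raw waist circumference as a comparator) can be thresholded by
    passing an extended mapping.
    """
    rules = dict(TERTILE_RULES) if rules is None else dict(rules)
    if len(panels) < 3:
        raise ValueError(f"need >= 3 panels to derive cutoffs, got {len(panels)}")
    cutoffs = {}
    for index_id, rule in rules.items():
        if index_id not in panels.columns:
            raise KeyError(f"panel frame lacks column {index_id!r}")
        col = panels[index_id].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise ValueError(f"NaN values in {index_id}")
        cutoffs[index_id] = tertile_cutoff(col, rule)
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(panels[list(rules)].to_numpy(float)).tobytes())
    return RiskCutoffSet(
        cutoffs=cutoffs, rules=rules,
        fingerprint=f"n={len(panels)}:{h.hexdigest()[:12]}",
    )


def risk_flags(panel, cutoffs: RiskCutoffSet):
    """Binary risk flags: value ≥ cutoff for tertile rules, value > 1 for PMI.

    Accepts one panel dict (returns dict of bool) or a panel DataFrame
    (returns a boolean DataFrame with the same rows).
    """
    if isinstance(panel, pd.DataFrame):
        out = {}
        for index_id, rule in cutoffs.rules.items():
            if index_id not in panel.columns:
                raise KeyError(f"panel frame lacks column {index_id!r}")
            v = panel[index_id].to_numpy(dtype=float)
            c = cutoffs.cutoffs[index_id]
            out[index_id] = v > c if rule == FIXED_GT_1 else v >= c
        return pd.DataFrame(out, index=panel.index)
    out = {}
    for index_id, rule in cutoffs.rules.items():
        if index_id not in panel:
            raise KeyError(f"panel lacks index {index_id!r}")
        v = panel[index_id]
        c = cutoffs.cutoffs[index_id]
        out[index_id] = bool(v > c) if rule == FIXED_GT_1 else bool(v >= c)
    return out
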