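"""The 19 anthropometric indices and cohort descriptive statistics.

Three traditional indices (BMI, WHR, WHtR) and sixteen emergent body-shape
indices are computed from raw measurements. Units are fixed here once:
waist enters in metres where a formula's published magnitude demands it
(WHtR, H3W3, wBMI, BRI, ABSI, CI) and in cm elsewhere; height is always in
metres; the PMI divisor is 1730.

All formulas are pure functions of a participant's fields and are evaluated
either on scalars (one record) or on whole columns (a cohort) by the same
code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from .cohort import Cohort

#: canonical index order (traditional first, then emergent)
INDEX_IDS = (
    "BMI", "WHR", "WHtR",
    "AWI", "HWrI", "WWrI", "WHHR", "WHT2", "WHT3", "H3W3",
    "WBMI", "PI", "BRI", "BAI", "ABSI", "CI", "BFDI", "AVI", "PMI",
)
TRADITIONAL = INDEX_IDS[:3]
EMERGENT = INDEX_IDS[3:]

#: display units, for table headers
UNITS = {
    "BMI": "kg/m^2", "WHR": "", "WHtR": "", "AWI": "", "HWrI": "",
    "WWrI": "", "WHHR": "1/m", "WHT2": "cm/m^2", "WHT3": "cm/m^3",
    "H3W3": "", "WBMI": "kg/m", "PI": "kg/m^3", "BRI": "", "BAI": "",
    "ABSI": "m^11/6 kg^-2/3", "CI": "AU", "BFDI": "m", "AVI": "L", "PMI": "",
}


class IndexDomainError(ValueError):
    """An index formula was evaluated outside its mathematical domain."""


def _evaluate(d: Mapping[str, object]) -> dict:
    """Evaluate every index on scalars or aligned arrays.

    ``d`` maps height_m, weight_kg, waist_cm, hip_cm, wrist_cm, arm_cm,
    pulse_bpm to values. Returns a dict index_id -> value(s).
    """
    h = np.asarray(d["height_m"], dtype=float)
    w = np.asarray(d["weight_kg"], dtype=float)
    waist = np.asarray(d["waist_cm"], dtype=float)
    hip = np.asarray(d["hip_cm"], dtype=float)
    wrist = np.asarray(d["wrist_cm"], dtype=float)
    arm = np.asarray(d["arm_cm"], dtype=float)
    pulse = np.asarray(d["pulse_bpm"], dtype=float)
    waist_m = waist / 100.0

    out: dict = {}
    out["BMI"] = bmi = w / h**2
    out["WHR"] = whr = waist / hip
    out["WHtR"] = waist_m / h
    out["AWI"] = waist / arm
    out["HWrI"] = hip / wrist
    out["WWrI"] = waist / wrist
    out["WHHR"] = whr / h
    out["WHT2"] = waist / h**2
    out["WHT3"] = waist / h**3
    out["H3W3"] = h**3 / waist_m**3
    out["WBMI"] = waist_m * bmi
    out["PI"] = w / h**3
    # body roundness: eccentricity of the ellipse with half-height h/2 and
    # radius waist/(2*pi); the sqrt argument is positive for physiologic input
    ecc = (waist_m / (2.0 * np.pi)) / (0.5 * h)
    arg = 1.0 - ecc**2
    if np.any(arg < 0):
        ids = np.asarray(d.get("id", "?"))
        bad = ids[np.atleast_1d(arg < 0)] if ids.shape else ids
        raise IndexDomainError(f"BRI sqrt argument negative for record(s) {bad}")
    out["BRI"] = 364.2 - 365.5 * np.sqrt(arg)
    out["BAI"] = hip / h**1.5 - 18.0
    out["ABSI"] = waist_m / (bmi ** (2.0 / 3.0) * h**0.5)
    out["CI"] = waist_m / (0.109 * np.sqrt(w / h))
    out["BFDI"] = ((waist / h) + (1.0 / h)) / whr
    out["AVI"] = (2.0 * waist**2 + 0.7 * (waist - hip) ** 2) / 1000.0
    out["PMI"] = pulse * bmi / 1730.0
    return out


def compute_index(record, index_id: str) -> float:
    """One index for one participant record."""
    if index_id not in INDEX_IDS:
        raise KeyError(f"unknown index {index_id!r}")
    d = {
        "id": record.id, "height_m": record.height, "weight_kg": record.weight,
        "waist_cm": record.waist, "hip_cm": record.hip, "wrist_cm": record.wrist,
        "arm_cm": record.arm, "pulse_bpm": record.pulse,
    }
    return float(_evaluate(d)[index_id])


def compute_panel(record) -> dict:
    """All 19 indices for one record, keyed by index id."""
    d = {
        "id": record.id, "height_m": record.height, "weight_kg": record.weight,
        "waist_cm": record.waist, "hip_cm": record.hip, "wrist_cm": record.wrist,
        "arm_cm": record.arm, "pulse_bpm": record.pulse,
    }
    vals = _evaluate(d)
    return {k: float(vals[k]) for k in INDEX_IDS}


def compute_panels(cohort: Cohort) -> pd.DataFrame:
    """Index panel for every participant: one row per id, 19 columns."""
    f = cohort.frame
    vals = _evaluate(
        {
            "id": f["id"].to_numpy(), "height_m": f["height_m"],
            "weight_kg": f["weight_kg"], "waist_cm": f["waist_cm"],
            "hip_cm": f["hip_cm"], "wrist_cm": f["wrist_cm"],
            "arm_cm": f["arm_cm"], "pulse_bpm": f["pulse_bpm"],
        }
    )
    panels = pd.DataFrame({k: np.asarray(vals[k]) for k in INDEX_IDS})
    panels.insert(0, "id", f["id"].to_numpy())
    return panels


def percentile(values: Sequence[float], p: float) -> float:
    """Percentile by linear interpolation between closest ranks, h=(n-1)p+1."""
    return float(np.quantile(np.asarray(values, dtype=float), p))


# raw columns reported alongside the indices in the descriptive table
_RAW_ROWS = [
    ("age_years", "Age (years)"),
    ("height_m", "Height (m)"),
    ("weight_kg", "Weight (kg)"),
    ("waist_cm", "WC (cm)"),
    ("body_fat_pct", "Body fat (%)"),
    ("visceral_fat", "Visceral fat"),
    ("sbp_mmhg", "SBP (mmHg)"),
    ("dbp_mmhg", "DBP (mmHg)"),
]


@dataclass
class DescriptiveTable:
    """Cohort descriptives: numeric rows and the blood-pressure category block."""

    numeric: pd.DataFrame
    categories: pd.DataFrame


def describe_indices(cohort: Cohort, by_sex: bool = True) -> DescriptiveTable:
    """Median (5th–95th percentile) per variable, overall and by sex.

    H3W3 is summarised as mean ± SD and compared between sexes with the
    pooled-variance t test; every other numeric row uses the median with
    5th–95th percentiles and the Mann–Whitney U test. The blood-pressure
    category block reports counts with percentages and a chi-squared test.
    Groups with fewer than 2 members get NaN dispersion fields.
    """
    from . import classify as _classify
    from . import stats as _stats

    if cohort.n == 0:
        raise ValueError("cannot describe an empty cohort")
    f = cohort.frame
    panels = compute_panels(cohort)
    groups = {"total": np.ones(len(f), dtype=bool)}
    if by_sex:
        groups["men"] = (f["sex"] == "male").to_numpy()
        groups["women"] = (f["sex"] == "female").to_numpy()

    def summarise(values: np.ndarray, mask: np.ndarray) -> dict:
        v = values[mask]
        v = v[~np.isnan(v)]
        if len(v) == 0:
            return dict.fromkeys(["median", "p5", "p95", "mean", "sd", "n"], np.nan)
        out = {"n": len(v), "median": float(np.median(v)),
               "mean": float(np.mean(v)),
               "sd": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan}
        if len(v) > 1:
            out["p5"], out["p95"] = percentile(v, 0.05), percentile(v, 0.95)
        else:
            out["p5"] = out["p95"] = out["median"]
        return out

    rows = []
    items = [(label, f[col].to_numpy(dtype=float)) for col, label in _RAW_ROWS]
    items += [(idx, panels[idx].to_numpy()) for idx in INDEX_IDS]
    for label, values in items:
        use_mean = label == "H3W3"
        row = {"variable": label, "summary": "mean_sd" if use_mean else "median_p5_p95"}
        for gname, mask in groups.items():
            s = summarise(values, mask)
            for k, v in s.items():
                row[f"{gname}_{k}"] = v
        if by_sex:
            a = values[groups["men"]]
            b = values[groups["women"]]
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            if len(a) >= 2 and len(b) >= 2:
                try:
                    if use_mean:
                        _, p = _stats.students_t(a, b)
                    else:
                        _, p = _stats.mann_whitney_u(a, b)
                except _stats.DegenerateInputError:
                    p = np.nan   # constant in both groups: no contrast
                row["p_value"] = p
            else:
                row["p_value"] = np.nan
        rows.append(row)
    numeric = pd.DataFrame(rows)

    cats = _classify.classify_bp_frame(f)
    order = ["normotensive", "prehypertension", "hypertension"]
    crows = []
    for cat in order:
        row = {"category": cat}
        for gname, mask in groups.items():
            count = int(((cats == cat) & mask).sum())
            total = int(mask.sum())
            row[f"{gname}_n"] = count
            row[f"{gname}_pct"] = 100.0 * count / total if total else np.nan
        crows.append(row)
    categories = pd.DataFrame(crows)
    if by_sex and groups["men"].any() and groups["women"].any():
        table = np.array(
            [[int(((cats == cat) & groups[g]).sum()) for cat in order]
             for g in ("men", "women")]
        )
        if (table.sum(axis=0) > 0).all():
            _, _, p = _stats.chi_square(table)
            categories.attrs["chi2_p"] = p
    return DescriptiveTable(numeric=numeric, categories=categories)
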