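"""Full study orchestration: descriptives, correlations, associations, AUC.

The analysis mirrors a screening-study design: risk cutoffs are derived
once on the full analysis cohort, blood pressure is categorised per JNC7,
and each binary risk flag is related to prehypertension (vs normotension)
and hypertension (vs normotension) with logistic models — adjusted for age
and sex in the pooled stratum, for age within sex and sex×age strata —
plus a covariate-adjusted AUC per index, outcome and stratum.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import classify as _classify
from . import indices as _indices
from . import stats as _stats
from .cohort import Cohort

logger = logging.getLogger("anthro")

OUTCOMES = ("preHTN", "HTN")
_CASE_CATEGORY = {"preHTN": "prehypertension", "HTN": "hypertension"}

#: comparator columns added when include_traditional is on; all use the
#: upper-tertile rule (higher central adiposity = risk)
TRADITIONAL_COMPARATORS = ("waist_cm", "BMI", "WHtR", "WHR", "visceral_fat")


class StudyConfig(BaseModel):
    """Run configuration for :func:`run_study`."""

    age_cut: int = Field(default=40, ge=18, le=80)
    bootstrap_reps: int = Field(default=1000, ge=0)
    seed: int = 0
    include_traditional: bool = False

    def adjustment(self, stratum: str) -> tuple[str, ...]:
        return ("age", "sex") if stratum == "total" else ("age",)


@dataclass
class StudyReport:
    descriptives: pd.DataFrame
    categories: pd.DataFrame
    correlations: pd.DataFrame
    associations: pd.DataFrame
    auc: pd.DataFrame
    cutoffs: _classify.RiskCutoffSet
    meta: dict = field(default_factory=dict)


def stratify(cohort: Cohort, config: StudyConfig) -> dict[str, np.ndarray]:
    """Boolean masks for total / sex / sex × age strata (cut goes to 'le')."""
    f = cohort.frame
    male = (f["sex"] == "male").to_numpy()
    le = (f["age_years"] <= config.age_cut).to_numpy()
    cut = config.age_cut
    return {
        "total": np.ones(len(f), dtype=bool),
        "men": male,
        "women": ~male,
        f"men_le{cut}": male & le,
        f"men_gt{cut}": male & ~le,
        f"women_le{cut}": ~male & le,
        f"women_gt{cut}": ~male & ~le,
    }


def _cell_seed(base_seed: int, *labels: str) -> int:
    """Stable per-cell seed: the same cell gets the same stream no matter
    which other cells run."""
    tag = "|".join(labels).encode()
    return int((base_seed * 2654435761 + zlib.crc32(tag)) % (2**31 - 1))


def _analysis_columns(cohort: Cohort, config: StudyConfig):
    """Panels, flags and per-subject covariates for the analysis cohort."""
    f = cohort.frame
    panels = _indices.compute_panels(cohort)
    values = panels.drop(columns="id").copy()
    rules = dict(_classify.TERTILE_RULES)
    if config.include_traditional:
        for col in TRADITIONAL_COMPARATORS:
            values[col] = (f[col] if col in f.columns else panels[col]).to_numpy(float)
            rules[col] = _classify.THIRD_TERTILE
    cutoffs = _classify.derive_cutoffs(values, rules=rules)
    flags = _classify.risk_flags(values, cutoffs)
    bp_cat = _classify.classify_bp_frame(f)
    covars = pd.DataFrame({
        "age": f["age_years"].to_numpy(float),
        "sex": (f["sex"] == "male").to_numpy(float),
    })
    return values, flags, cutoffs, bp_cat, covars


def _fit_cell(y, flag, covars, adjust):
    X = np.column_stack([np.ones(len(y)), flag]
                        + [covars[c].to_numpy() for c in adjust])
    return _stats.fit_logistic(np.asarray(y, float), X)


def run_associations(
    cohort: Cohort,
    config: Optional[StudyConfig] = None,
    strata: Optional[dict[str, np.ndarray]] = None,
) -> pd.DataFrame:
    """Per-index odds ratios for preHTN and HTN (each vs normotensive)."""
    config = config or StudyConfig()
    values, flags, cutoffs, bp_cat, covars = _analysis_columns(cohort, config)
    strata = strata if strata is not None else stratify(cohort, config)
    rows = []
    for sname, smask in strata.items():
        adjust = config.adjustment(sname)
        for outcome in OUTCOMES:
            case_mask = (bp_cat == _CASE_CATEGORY[outcome]).to_numpy()
            ctrl_mask = (bp_cat == "normotensive").to_numpy()
            sel = smask & (case_mask | ctrl_mask)
            y = case_mask[sel].astype(float)
            for index_id in flags.columns:
                n_cases = int(y.sum())
                n_controls = int(len(y) - y.sum())
                if n_cases == 0 or n_controls == 0:
                    res = _stats.AssociationResult(
                        index_id=index_id, outcome=outcome, stratum=sname,
                        odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                        p_value=np.nan, n_cases=n_cases, n_controls=n_controls,
                        adjusted_for=adjust, defined=False,
                        reason="single_class_stratum",
                    )
                else:
                    fit = _fit_cell(y, flags[index_id].to_numpy(float)[sel],
                                    covars[sel], adjust)
                    res = _stats.odds_ratio(
                        fit, term=1, index_id=index_id, outcome=outcome,
                        stratum=sname, n_cases=n_cases, n_controls=n_controls,
                        adjusted_for=adjust,
                    )
                rows.append(res.__dict__ | {"adjusted_for": "+".join(adjust)})
    return pd.DataFrame(rows)


def run_correlations(cohort: Cohort, config: Optional[StudyConfig] = None) -> pd.DataFrame:
    """Spearman correlation of each index with SBP and DBP, total and by sex."""
    config = config or StudyConfig()
    f = cohort.frame
    panels = _indices.compute_panels(cohort)
    masks = {"total": np.ones(len(f), bool),
             "men": (f["sex"] == "male").to_numpy(),
             "women": (f["sex"] == "female").to_numpy()}
    rows = []
    for sname, mask in masks.items():
        for target in ("sbp_mmhg", "dbp_mmhg"):
            tv = f[target].to_numpy(float)[mask]
            for index_id in _indices.INDEX_IDS:
                iv = panels[index_id].to_numpy()[mask]
                if len(iv) < 3 or np.ptp(iv) == 0 or np.ptp(tv) == 0:
                    rho = p = np.nan
                else:
                    rho, p = _stats.spearman_rho(iv, tv)
                rows.append({"stratum": sname, "target": target.split("_")[0],
                             "index_id": index_id, "rho": rho, "p_value": p})
    return pd.DataFrame(rows)


def run_study(cohort: Cohort, config: Optional[StudyConfig] = None) -> StudyReport:
    """Execute the full analysis; deterministic for fixed cohort + config."""
    config = config or StudyConfig()
    if cohort.n == 0:
        raise ValueError("cannot analyse an empty cohort")
    bp_cat = _classify.classify_bp_frame(cohort.frame)
    if bp_cat.nunique() < 2:
        raise ValueError("cohort must contain at least 2 blood-pressure categories")

    desc = _indices.describe_indices(cohort, by_sex=True)
    values, flags, cutoffs, bp_cat, covars = _analysis_columns(cohort, config)
    strata = stratify(cohort, config)
    logger.info("run_study: n=%d, %d indices, strata=%s",
                cohort.n, flags.shape[1], list(strata))

    correlations = run_correlations(cohort, config)
    associations = run_associations(cohort, config, strata)

    auc_rows = []
    for sname, smask in strata.items():
        adjust = config.adjustment(sname)
        extra = covars[["sex"]].to_numpy() if "sex" in adjust else None
        for outcome in OUTCOMES:
            case_mask = (bp_cat == _CASE_CATEGORY[outcome]).to_numpy()
            ctrl_mask = (bp_cat == "normotensive").to_numpy()
            sel = smask & (case_mask | ctrl_mask)
            y = case_mask[sel].astype(float)
            for index_id in flags.columns:
                res = _stats.adjusted_auc(
                    flag=flags[index_id].to_numpy(float)[sel],
                    age=covars["age"].to_numpy()[sel],
                    outcome=y,
                    bootstrap_reps=config.bootstrap_reps,
                    seed=_cell_seed(config.seed, sname, outcome, index_id),
                    extra_covariates=None if extra is None else extra[sel],
                    index_id=index_id, outcome_label=outcome, stratum=sname,
                )
                auc_rows.append(res.__dict__ | {"adjusted_for": "+".join(adjust)})
    auc_table = pd.DataFrame(auc_rows)
    # rank-ordered within stratum × outcome, undefined cells last
    auc_table = auc_table.sort_values(
        ["stratum", "outcome", "auc"], ascending=[True, True, False],
        na_position="last", kind="mergesort",
    ).reset_index(drop=True)

    meta = {
        "n": cohort.n,
        "seed": config.seed,
        "config": config.model_dump(),
        "cutoffs": cutoffs.to_dict(),
        "n_dropped": getattr(cohort.validation, "n_dropped", 0)
        if cohort.validation else 0,
        "bp_counts": bp_cat.value_counts().to_dict(),
    }
    return StudyReport(descriptives=desc.numeric, categories=desc.categories,
                       correlations=correlations, associations=associations,
                       auc=auc_table, cutoffs=cutoffs, meta=meta)


def write_report(report: StudyReport, outdir: str | Path) -> None:
    """Write the report tables and run metadata under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.descriptives.to_csv(outdir / "descriptives.csv", index=False)
    report.categories.to_csv(outdir / "bp_categories.csv", index=False)
    report.correlations.to_csv(outdir / "correlations.csv", index=False)
    for outcome in OUTCOMES:
        sub = report.associations[report.associations["outcome"] == outcome]
        sub.to_csv(outdir / f"associations_{outcome}.csv", index=False)
    auc = report.auc
    auc[auc["stratum"] == "total"].to_csv(outdir / "auc_total.csv", index=False)
    auc[auc["stratum"].isin(["men", "women"])].to_csv(
        outdir / "auc_by_sex.csv", index=False)
    auc[~auc["stratum"].isin(["total", "men", "women"])].to_csv(
        outdir / "auc_by_sex_age.csv", index=False)
    with open(outdir / "cutoffs.json", "w") as fh:
        json.dump(report.cutoffs.to_dict(), fh, indent=2)
    with open(outdir / "run_meta.json", "w") as fh:
        json.dump(report.meta, fh, indent=2, default=str)
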