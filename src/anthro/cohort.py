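"""Cohort container, participant record validation and CSV round-trip.

One row per participant. Canonical units at the file boundary: height in
metres, circumferences in cm, weight in kg, pressures in mmHg, pulse in
beats/min. Booleans are written as 0/1; optional fields may be empty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, field_validator, model_validator

logger = logging.getLogger("anthro")

#: canonical CSV column order
COLUMNS = [
    "id", "sex", "age_years", "height_m", "weight_kg", "waist_cm", "hip_cm",
    "wrist_cm", "arm_cm", "body_fat_pct", "visceral_fat", "sbp_mmhg",
    "dbp_mmhg", "pulse_bpm", "antihypertensive", "smoker", "alcohol",
    "sedentary",
]

OPTIONAL_NUMERIC = ["body_fat_pct", "visceral_fat"]
OPTIONAL_BOOL = ["smoker", "alcohol", "sedentary"]
REQUIRED_COLUMNS = [c for c in COLUMNS if c not in OPTIONAL_NUMERIC + OPTIONAL_BOOL]

# open intervals for physiologic plausibility; age closed by eligibility
RANGES = {
    "height_m": (1.2, 2.2),
    "weight_kg": (30.0, 250.0),
    "waist_cm": (40.0, 220.0),
    "hip_cm": (40.0, 220.0),
    "wrist_cm": (8.0, 30.0),
    "arm_cm": (15.0, 60.0),
    "sbp_mmhg": (70.0, 260.0),
    "dbp_mmhg": (40.0, 160.0),
    "pulse_bpm": (30.0, 220.0),
}
AGE_BOUNDS = (18, 80)


class CohortSchemaError(ValueError):
    """The input file does not match the cohort schema."""


class RecordValidationError(ValueError):
    """A participant record violates a physiologic or logical invariant."""


class ParticipantRecord(BaseModel):
    """A single participant's raw measurements and blood-pressure status."""

    id: str
    sex: Literal["female", "male"]
    age: int
    height: float
    weight: float
    waist: float
    hip: float
    wrist: float
    arm: float
    sbp: float
    dbp: float
    pulse: float
    on_antihypertensive: bool
    body_fat: Optional[float] = None
    visceral_fat: Optional[float] = None
    smoker: Optional[bool] = None
    alcohol: Optional[bool] = None
    sedentary: Optional[bool] = None

    @field_validator("age")
    @classmethod
    def _age_in_bounds(cls, v: int) -> int:
        lo, hi = AGE_BOUNDS
        if not lo <= v <= hi:
            raise ValueError(f"age {v} outside [{lo}, {hi}]")
        return v

    @model_validator(mode="after")
    def _physiologic(self) -> "ParticipantRecord":
        for attr, col in _FIELD_TO_COLUMN.items():
            if col not in RANGES:
                continue
            lo, hi = RANGES[col]
            v = getattr(self, attr)
            if not lo < v < hi:
                raise ValueError(f"{attr}={v} outside ({lo}, {hi})")
        if not self.dbp < self.sbp:
            raise ValueError(f"dbp {self.dbp} must be < sbp {self.sbp}")
        return self


_FIELD_TO_COLUMN = {
    "id": "id", "sex": "sex", "age": "age_years", "height": "height_m",
    "weight": "weight_kg", "waist": "waist_cm", "hip": "hip_cm",
    "wrist": "wrist_cm", "arm": "arm_cm", "body_fat": "body_fat_pct",
    "visceral_fat": "visceral_fat", "sbp": "sbp_mmhg", "dbp": "dbp_mmhg",
    "pulse": "pulse_bpm", "on_antihypertensive": "antihypertensive",
    "smoker": "smoker", "alcohol": "alcohol", "sedentary": "sedentary",
}
_COLUMN_TO_FIELD = {v: k for k, v in _FIELD_TO_COLUMN.items()}


@dataclass
class ValidationSummary:
    n_read: int = 0
    n_valid: int = 0
    n_dropped: int = 0
    reasons: dict = field(default_factory=dict)  # id -> reason string


@dataclass
class Cohort:
    """An ordered collection of participants backed by a DataFrame.

    The frame uses the canonical CSV columns (see :data:`COLUMNS`); ids are
    unique. ``provenance`` records where the data came from (a file path or
    generator parameters plus seed).
    """

    frame: pd.DataFrame
    provenance: Optional[dict] = None
    validation: Optional[ValidationSummary] = None

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise CohortSchemaError(f"missing column(s): {', '.join(missing)}")
        self.frame = self.frame[COLUMNS].reset_index(drop=True)
        ids = self.frame["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise RecordValidationError(f"duplicate participant id {dup!r}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n(self) -> int:
        return len(self.frame)

    def to_records(self) -> list[ParticipantRecord]:
        out = []
        for row in self.frame.to_dict("records"):
            kwargs = {}
            for col, val in row.items():
                f = _COLUMN_TO_FIELD[col]
                if col in OPTIONAL_NUMERIC + OPTIONAL_BOOL and (
                    val is None or (isinstance(val, float) and np.isnan(val))
                ):
                    kwargs[f] = None
                elif col == "antihypertensive" or col in OPTIONAL_BOOL:
                    kwargs[f] = bool(val)
                elif col == "age_years":
                    kwargs[f] = int(val)
                else:
                    kwargs[f] = val
            out.append(ParticipantRecord(**kwargs))
        return out

    @classmethod
    def from_records(
        cls, records: Iterable[ParticipantRecord], provenance: Optional[dict] = None
    ) -> "Cohort":
        rows = []
        for r in records:
            rows.append({col: getattr(r, f) for f, col in _FIELD_TO_COLUMN.items()})
        frame = pd.DataFrame(rows, columns=COLUMNS)
        return cls(frame=frame, provenance=provenance)


def validate_frame(frame: pd.DataFrame) -> pd.Series:
    """Vectorised validation; returns one reason string per row ('' = valid).

    The predicates are pure and identical to :class:`ParticipantRecord`'s:
    the same row always gets the same verdict.
    """
    reasons = pd.Series("", index=frame.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    for col in REQUIRED_COLUMNS:
        if col in ("id", "sex"):
            flag(frame[col].isna() | (frame[col].astype(str).str.len() == 0),
                 f"missing {col}")
        else:
            flag(pd.to_numeric(frame[col], errors="coerce").isna(),
                 f"missing or non-numeric {col}")

    sex = frame["sex"].astype(str).str.lower()
    flag(~sex.isin(["female", "male"]), "sex not female/male")

    age = pd.to_numeric(frame["age_years"], errors="coerce")
    flag((age < AGE_BOUNDS[0]) | (age > AGE_BOUNDS[1]) | (age % 1 != 0),
         "age outside [18, 80] or non-integral")

    for col, (lo, hi) in RANGES.items():
        v = pd.to_numeric(frame[col], errors="coerce")
        flag((v <= lo) | (v >= hi), f"{col} outside ({lo}, {hi})")

    sbp = pd.to_numeric(frame["sbp_mmhg"], errors="coerce")
    dbp = pd.to_numeric(frame["dbp_mmhg"], errors="coerce")
    flag(dbp >= sbp, "dbp >= sbp")
    return reasons


def _coerce_types(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    frame["id"] = frame["id"].astype(str)
    frame["sex"] = frame["sex"].astype(str).str.lower()
    frame["age_years"] = frame["age_years"].astype(int)
    for col in COLUMNS[3:14]:
        frame[col] = frame[col].astype(float)
    frame["antihypertensive"] = frame["antihypertensive"].astype(float).astype(int)
    for col in OPTIONAL_BOOL:
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    return frame


def read_cohort(path: str | Path, strict: bool = False) -> Cohort:
    """Read a cohort CSV, validating every row.

    With ``strict=False`` invalid rows are dropped and counted in the
    returned cohort's ``validation`` summary; with ``strict=True`` the first
    invalid row raises :class:`RecordValidationError`.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"id": str})
    if frame.empty and len(frame.columns) == 0:
        raise CohortSchemaError(f"{path}: empty file")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    for col in OPTIONAL_BOOL + OPTIONAL_NUMERIC:
        if col not in frame.columns:
            frame[col] = np.nan

    reasons = validate_frame(frame)
    bad = reasons != ""
    if bad.any() and strict:
        i = bad.idxmax()
        raise RecordValidationError(
            f"{path}: row {i} (id={frame.loc[i, 'id']!r}): {reasons[i]}"
        )
    summary = ValidationSummary(
        n_read=len(frame),
        n_valid=int((~bad).sum()),
        n_dropped=int(bad.sum()),
        reasons={str(frame.loc[i, "id"]): reasons[i] for i in frame.index[bad]},
    )
    if summary.n_dropped:
        logger.info(
            "read_cohort: dropped %d/%d invalid row(s) from %s",
            summary.n_dropped, summary.n_read, path,
        )
    frame = _coerce_types(frame[~bad])
    cohort = Cohort(frame=frame, provenance={"source": str(path)})
    cohort.validation = summary
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort CSV in canonical column order, losslessly re-readable."""
    out = cohort.frame[COLUMNS].copy()
    for col in OPTIONAL_BOOL:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False, float_format="%.12g")
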