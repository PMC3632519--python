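"""Participant records, cohort container and CSV input/output.

A cohort is a participant-level table from a cross-sectional health
examination: demographics, self-reported diabetes and family history,
fasting glucose, medication use, smoking, physical-activity categories
and anthropometrics.  The on-disk format is UTF-8 CSV (RFC-4180) with a
documented default header; arbitrary column names are adapted through a
user-supplied codebook (canonical name -> file column name).

Missing-value convention: an empty cell in the CSV.  Internally a
missing value is ``NaN`` / ``pd.NA`` (numeric and ordinal columns) or
``NaN`` (categorical object columns); the self-reported-diabetes item
uses the explicit category ``"blank"`` for an unanswered question,
because a blank answer participates in the outcome-classification rule
and is therefore not ordinary missing data.  Decimal separator is always
``"."``; no locale inference is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ParticipantRecord",
    "Cohort",
    "SchemaError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "DEFAULT_COLUMNS",
    "OPTIONAL_COLUMNS",
]


class SchemaError(ValueError):
    """A required column is absent from the input file."""


class ValidationError(ValueError):
    """A cell violates the codebook's value constraints."""


#: Canonical core columns, in on-disk order.
DEFAULT_COLUMNS = (
    "id",
    "sex",
    "selfreport_diabetes",
    "fasting_glucose",
    "antidiabetic_medication",
    "mother_diabetes",
    "father_diabetes",
    "sibling_diabetes",
    "smoking",
    "leisure_pa",
    "work_sedentary",
    "height",
    "weight",
    "waist",
    "hip",
    "sad",
)

#: Best-effort descriptive extras carried through I/O when present.
OPTIONAL_COLUMNS = (
    "insulin",
    "hdl",
    "ldl",
    "triglycerides",
    "systolic_bp",
    "diastolic_bp",
)

_NUMERIC = (
    "fasting_glucose",
    "height",
    "weight",
    "waist",
    "hip",
    "sad",
) + OPTIONAL_COLUMNS
_ORDINAL = ("leisure_pa", "work_sedentary")

_ENUMS = {
    "sex": ("male", "female"),
    "selfreport_diabetes": ("yes", "no", "blank"),
    "antidiabetic_medication": ("yes", "no"),
    "mother_diabetes": ("yes", "no"),
    "father_diabetes": ("yes", "no"),
    "sibling_diabetes": ("yes", "no"),
    "smoking": ("current", "ex", "never"),
}
# Categorical columns where an empty cell is permitted and means "missing"
# (for selfreport_diabetes an empty cell maps to the category "blank").
_ENUM_MISSING_OK = ("smoking",)


@dataclass(frozen=True)
class ParticipantRecord:
    """One subject's raw questionnaire and examination values."""

    id: str
    sex: str
    selfreport_diabetes: str = "blank"
    fasting_glucose: Optional[float] = None
    antidiabetic_medication: str = "no"
    mother_diabetes: str = "no"
    father_diabetes: str = "no"
    sibling_diabetes: str = "no"
    smoking: Optional[str] = None
    leisure_pa: Optional[int] = None
    work_sedentary: Optional[int] = None
    height: Optional[float] = None
    weight: Optional[float] = None
    waist: Optional[float] = None
    hip: Optional[float] = None
    sad: Optional[float] = None


@dataclass
class Cohort:
    """Ordered collection of participant records with provenance.

    The table is held as a :class:`pandas.DataFrame` in canonical column
    order; ``parse_report`` counts, per column, the cells that could not
    be parsed as numbers and were coerced to missing.
    """

    df: pd.DataFrame
    provenance: str = ""
    parse_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_cohort(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> Iterator[ParticipantRecord]:
        """Yield typed records (row-wise view of the table)."""
        for _, row in self.df.iterrows():
            yield ParticipantRecord(
                id=str(row["id"]),
                sex=row["sex"],
                selfreport_diabetes=row["selfreport_diabetes"],
                fasting_glucose=_opt_float(row["fasting_glucose"]),
                antidiabetic_medication=row["antidiabetic_medication"],
                mother_diabetes=row["mother_diabetes"],
                father_diabetes=row["father_diabetes"],
                sibling_diabetes=row["sibling_diabetes"],
                smoking=None if pd.isna(row["smoking"]) else row["smoking"],
                leisure_pa=_opt_int(row["leisure_pa"]),
                work_sedentary=_opt_int(row["work_sedentary"]),
                height=_opt_float(row["height"]),
                weight=_opt_float(row["weight"]),
                waist=_opt_float(row["waist"]),
                hip=_opt_float(row["hip"]),
                sad=_opt_float(row["sad"]),
            )

    @classmethod
    def from_records(
        cls, records: list[ParticipantRecord], provenance: str = "from_records"
    ) -> "Cohort":
        rows = []
        for r in records:
            d = r.__dict__.copy()
            if d["smoking"] is None:
                d["smoking"] = np.nan
            rows.append(d)
        df = pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS))
        for col in _NUMERIC:
            if col in df.columns:
                df[col] = pd.to_numeric(df[col])
        for col in _ORDINAL:
            df[col] = pd.array(df[col], dtype="Int64")
        return cls(df=df, provenance=provenance)


def _opt_float(v) -> Optional[float]:
    return None if pd.isna(v) else float(v)


def _opt_int(v) -> Optional[int]:
    return None if pd.isna(v) else int(v)


def validate_cohort(df: pd.DataFrame) -> None:
    """Raise :class:`ValidationError` on constraint violations."""
    if len(df) == 0:
        raise ValidationError("cohort is empty")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValidationError(f"duplicate participant id: {dup!r}")
    for col, allowed in _ENUMS.items():
        vals = df[col].dropna()
        bad = ~vals.isin(allowed)
        if bad.any():
            raise ValidationError(
                f"column {col!r}: value {vals[bad].iloc[0]!r} not in {allowed}"
            )
        if col not in _ENUM_MISSING_OK and col != "smoking" and df[col].isna().any():
            raise ValidationError(f"column {col!r} does not admit missing values")
    for col in _ORDINAL:
        vals = pd.array(df[col], dtype="Int64").dropna()
        if len(vals) and ((vals < 1) | (vals > 4)).any():
            raise ValidationError(f"column {col!r}: ordinal values must be in 1..4")
    for col in _NUMERIC:
        if col not in df.columns:
            continue
        vals = df[col].dropna()
        if len(vals) and (vals <= 0).any():
            raise ValidationError(
                f"column {col!r}: values must be strictly positive when present"
            )


def read_cohort(
    path: str | Path, codebook: Mapping[str, str] | None = None
) -> Cohort:
    """Read a cohort CSV, adapting column names through ``codebook``.

    ``codebook`` maps canonical names (see :data:`DEFAULT_COLUMNS`) to
    the column names found in the file; omitted entries default to the
    canonical name itself.  Unparseable numeric cells are coerced to
    missing and tallied in ``Cohort.parse_report``.
    """
    path = Path(path)
    codebook = dict(codebook or {})
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)

    df = pd.DataFrame(index=raw.index)
    for canon in DEFAULT_COLUMNS:
        src = codebook.get(canon, canon)
        if src not in raw.columns:
            raise SchemaError(f"required column missing: {src!r} (for {canon!r})")
        df[canon] = raw[src]
    for canon in OPTIONAL_COLUMNS:
        src = codebook.get(canon, canon)
        if src in raw.columns:
            df[canon] = raw[src]

    def _parse_floats(s: pd.Series) -> tuple[pd.Series, int]:
        # float() is correctly rounded, so repr-written values round-trip
        vals = np.empty(len(s), dtype=float)
        bad = 0
        for i, cell in enumerate(s.to_numpy()):
            if cell == "":
                vals[i] = np.nan
                continue
            try:
                vals[i] = float(cell)
            except ValueError:
                vals[i] = np.nan
                bad += 1
        return pd.Series(vals, index=s.index), bad

    report: dict[str, int] = {}
    for col in df.columns:
        s = df[col].str.strip()
        if col in _NUMERIC:
            out, bad = _parse_floats(s)
            report[col] = bad
            df[col] = out
        elif col in _ORDINAL:
            out = pd.to_numeric(s.replace("", np.nan), errors="coerce")
            report[col] = int((s != "").sum() - out.notna().sum())
            df[col] = pd.array(np.floor(out), dtype="Int64")
        elif col == "selfreport_diabetes":
            df[col] = s.replace("", "blank")
        elif col == "smoking":
            df[col] = s.replace("", np.nan)
        else:
            df[col] = s
    report = {k: v for k, v in report.items() if v}
    return Cohort(df=df, provenance=str(path), parse_report=report)


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort to CSV so that a read-back reproduces every field.

    Field order is fixed (core columns, then any extras present) and
    missing values are written as empty cells, so output is byte-stable
    for a given cohort.
    """
    path = Path(path)
    cols = [c for c in DEFAULT_COLUMNS] + [
        c for c in OPTIONAL_COLUMNS if c in cohort.df.columns
    ]
    out = cohort.df[cols].copy()
    out["selfreport_diabetes"] = out["selfreport_diabetes"].replace("blank", "")
    for col in _NUMERIC:
        if col in out.columns:
            # shortest round-trip representation, so read(write(c)) == c
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False, na_rep="")
    return path
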