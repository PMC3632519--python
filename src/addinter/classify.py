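"""Outcome classification and exposure derivation.

Outcome
-------
Participants are classified into one of four mutually exclusive classes:

* ``diabetes`` — self-reported diabetes, or fasting glucose >= 7.0
  mmol/l, or reported use of antidiabetic medication;
* ``prediabetes`` — impaired fasting glucose, 6.1-6.9 mmol/l, in the
  absence of the diabetes criteria;
* ``reference`` — neither of the above, glucose below 6.1 mmol/l (or a
  negative self-report with no measurement);
* ``excluded`` — no glucose value registered *and* the diabetes question
  left blank (with no antidiabetic medication), so no criterion can be
  evaluated.

Unrounded glucose values in the open interval (6.9, 7.0) are assigned to
prediabetes, i.e. the impaired-fasting-glucose band is implemented as
[6.1, 7.0): the conventional 6.1-6.9 statement presumes values reported
to one decimal.

Exposures
---------
All exposures are dichotomous.  Parental history of diabetes (PHD) is
diabetes in either parent; the maternal-history analysis set excludes
subjects reporting a paternal history (and vice versa), expressed here
through eligibility flags.  Current smoking is contrasted with never/ex
smoking; leisure-time and work inactivity are level 1 of their
four-level questionnaire items; BMI is dichotomised at >25 (overweight)
and >30 (obesity); sagittal abdominal diameter (SAD), waist
circumference, waist-to-hip ratio (WHR) and BMI are additionally
dichotomised at sex-specific 90th-percentile cutoffs ("high" means
strictly above the cutoff).  Missing raw fields propagate to missing
exposure flags; no imputation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .cohort import Cohort, ParticipantRecord

__all__ = [
    "OutcomeClass",
    "classify_outcome",
    "classify_cohort",
    "derive_bmi",
    "percentile_cutoff",
    "Cutoffs",
    "default_cutoffs",
    "derive_exposures",
    "ClassifiedCohort",
    "classify_and_derive",
]

GLUCOSE_DIABETES = 7.0  # mmol/l, inclusive
GLUCOSE_IFG_LOW = 6.1  # mmol/l, inclusive


class OutcomeClass(str, Enum):
    diabetes = "diabetes"
    prediabetes = "prediabetes"
    reference = "reference"
    excluded = "excluded"


def classify_outcome(record: ParticipantRecord) -> OutcomeClass:
    """Classify a single participant (pure, total function)."""
    g = record.fasting_glucose
    if (
        record.selfreport_diabetes == "yes"
        or record.antidiabetic_medication == "yes"
        or (g is not None and g >= GLUCOSE_DIABETES)
    ):
        return OutcomeClass.diabetes
    if g is None:
        if record.selfreport_diabetes == "blank":
            return OutcomeClass.excluded
        return OutcomeClass.reference  # answered "no", no measurement
    if GLUCOSE_IFG_LOW <= g < GLUCOSE_DIABETES:
        return OutcomeClass.prediabetes
    return OutcomeClass.reference


def classify_cohort(cohort: Union[Cohort, pd.DataFrame]) -> pd.Series:
    """Vectorised outcome classification; returns a Categorical series."""
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    g = df["fasting_glucose"].to_numpy(dtype=float)
    sr = df["selfreport_diabetes"].to_numpy()
    med = df["antidiabetic_medication"].to_numpy()

    has_g = ~np.isnan(g)
    diab = (sr == "yes") | (med == "yes") | (has_g & (g >= GLUCOSE_DIABETES))
    pre = ~diab & has_g & (g >= GLUCOSE_IFG_LOW) & (g < GLUCOSE_DIABETES)
    excl = ~diab & ~has_g & (sr == "blank")
    out = np.full(len(df), OutcomeClass.reference.value, dtype=object)
    out[diab] = OutcomeClass.diabetes.value
    out[pre] = OutcomeClass.prediabetes.value
    out[excl] = OutcomeClass.excluded.value
    return pd.Series(
        pd.Categorical(out, categories=[c.value for c in OutcomeClass]),
        index=df.index,
        name="outcome",
    )


def derive_bmi(height_cm, weight_kg):
    """Body mass index, weight / (height in m)^2; missing propagates."""
    if height_cm is None or weight_kg is None:
        return None
    if np.isscalar(height_cm) and (np.isnan(height_cm) or np.isnan(weight_kg)):
        return float("nan")
    if np.isscalar(height_cm) and (height_cm <= 0 or weight_kg <= 0):
        raise ValueError("height and weight must be strictly positive")
    return weight_kg / (height_cm / 100.0) ** 2


def percentile_cutoff(
    values: pd.Series, groups: pd.Series, q: float = 0.9, min_n: int = 10
) -> dict:
    """Per-group percentile cutoff (linear interpolation, 'type 7').

    A measurement counts as "high" when strictly above its group's
    cutoff.  Raises if a group has fewer than ``min_n`` non-missing
    values, naming the group.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    out = {}
    for grp in pd.unique(groups.dropna()):
        v = values[groups == grp].dropna().to_numpy(dtype=float)
        if len(v) < min_n:
            raise ValueError(
                f"group {grp!r}: only {len(v)} non-missing values (need {min_n})"
            )
        out[grp] = float(np.quantile(v, q))  # default = linear interpolation
    return out


@dataclass
class Cutoffs:
    """Sex-specific upper-decile cutoffs for the adiposity measures."""

    q: float = 0.9
    sad: dict = field(default_factory=dict)
    waist: dict = field(default_factory=dict)
    whr: dict = field(default_factory=dict)
    bmi: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "q": self.q,
            "sad": self.sad,
            "waist": self.waist,
            "whr": self.whr,
            "bmi": self.bmi,
        }


def default_cutoffs(df: pd.DataFrame, q: float = 0.9) -> Cutoffs:
    """Compute sex-specific 90th-percentile cutoffs from the cohort."""
    sex = df["sex"]
    whr = df["waist"] / df["hip"]
    return Cutoffs(
        q=q,
        sad=percentile_cutoff(df["sad"], sex, q),
        waist=percentile_cutoff(df["waist"], sex, q),
        whr=percentile_cutoff(whr, sex, q),
        bmi=percentile_cutoff(
            df["weight"] / (df["height"] / 100.0) ** 2, sex, q
        ),
    )


def _flag_gt(values: pd.Series, sex: pd.Series, cut: Mapping) -> pd.arrays.BooleanArray:
    """value > sex-specific cutoff, NA where the value is missing."""
    thr = sex.map(cut).to_numpy(dtype=float)
    v = values.to_numpy(dtype=float)
    res = pd.array(v > thr, dtype="boolean")
    res[np.isnan(v)] = pd.NA
    return res


def derive_exposures(
    cohort: Union[Cohort, pd.DataFrame, ParticipantRecord],
    cutoffs: Optional[Cutoffs] = None,
) -> pd.DataFrame:
    """Derive the panel of dichotomous exposures for every record.

    Returns a DataFrame of nullable-boolean flags plus the continuous
    ``bmi`` and ``whr`` columns.  ``cutoffs`` supplies the sex-specific
    upper-decile thresholds for the ``high_*`` flags; when omitted they
    are computed from the cohort itself (requires >= 10 non-missing
    values per sex for each measure).
    """
    if isinstance(cohort, ParticipantRecord):
        df = Cohort.from_records([cohort]).df
    else:
        df = cohort.df if isinstance(cohort, Cohort) else cohort

    panel = pd.DataFrame(index=df.index)
    mother = df["mother_diabetes"] == "yes"
    father = df["father_diabetes"] == "yes"
    sib = df["sibling_diabetes"] == "yes"
    panel["phd"] = pd.array(mother | father, dtype="boolean")
    panel["maternal_history"] = pd.array(mother, dtype="boolean")
    panel["maternal_eligible"] = pd.array(~father, dtype="boolean")
    panel["paternal_history"] = pd.array(father, dtype="boolean")
    panel["paternal_eligible"] = pd.array(~mother, dtype="boolean")
    panel["biparental"] = pd.array(mother & father, dtype="boolean")
    panel["family_history"] = pd.array(mother | father | sib, dtype="boolean")

    smoking = df["smoking"]
    cur = pd.array(smoking == "current", dtype="boolean")
    cur[smoking.isna()] = pd.NA
    ex = pd.array(smoking == "ex", dtype="boolean")
    ex[smoking.isna()] = pd.NA
    panel["current_smoker"] = cur
    panel["ex_smoker"] = ex

    for src, dst in (("leisure_pa", "leisure_inactive"), ("work_sedentary", "work_inactive")):
        lv = pd.array(df[src], dtype="Int64")
        flag = pd.array(lv == 1, dtype="boolean")
        flag[lv.isna()] = pd.NA
        panel[dst] = flag

    bmi = df["weight"] / (df["height"] / 100.0) ** 2
    panel["bmi"] = bmi
    for thr, dst in ((25.0, "bmi_gt25"), (30.0, "bmi_gt30")):
        flag = pd.array(bmi.to_numpy(dtype=float) > thr, dtype="boolean")
        flag[bmi.isna().to_numpy()] = pd.NA
        panel[dst] = flag

    panel["whr"] = df["waist"] / df["hip"]

    if cutoffs is None:
        cutoffs = default_cutoffs(df)
    sex = df["sex"]
    panel["high_sad"] = _flag_gt(df["sad"], sex, cutoffs.sad)
    panel["high_waist"] = _flag_gt(df["waist"], sex, cutoffs.waist)
    panel["high_whr"] = _flag_gt(panel["whr"], sex, cutoffs.whr)
    panel["high_bmi_p90"] = _flag_gt(panel["bmi"], sex, cutoffs.bmi)
    return panel


@dataclass
class ClassifiedCohort:
    """A cohort together with its outcome classes and exposure panel.

    This is the working object of the downstream odds-ratio and
    interaction analyses.
    """

    cohort: Cohort
    outcome: pd.Series
    panel: pd.DataFrame
    cutoffs: Cutoffs

    @property
    def df(self) -> pd.DataFrame:
        return self.cohort.df

    def counts(self) -> dict:
        c = self.outcome.value_counts().to_dict()
        return {k.value if isinstance(k, OutcomeClass) else str(k): int(v) for k, v in c.items()}


def classify_and_derive(
    cohort: Cohort, cutoffs: Optional[Cutoffs] = None
) -> ClassifiedCohort:
    """Run outcome classification and exposure derivation on a cohort."""
    outcome = classify_cohort(cohort)
    if cutoffs is None:
        cutoffs = default_cutoffs(cohort.df)
    panel = derive_exposures(cohort, cutoffs)
    return ClassifiedCohort(cohort=cohort, outcome=outcome, panel=panel, cutoffs=cutoffs)
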