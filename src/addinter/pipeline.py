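"""End-to-end orchestration and reporting.

Three report stages mirror the shape of a classical cross-sectional
analysis:

* a descriptive table (per sex, outcome classes vs the reference
  class, with chi-square / t / Kruskal-Wallis p-values as appropriate);
* a prevalence odds-ratio table for the family-history exposures,
  crude and adjusted, per sex and both sexes combined;
* an additive-interaction table for parental history paired with each
  lifestyle/adiposity exposure, per sex, with synergy indices.

Reports are emitted in two layers: full-precision JSON for downstream
computation, and a human-readable TSV rounded to one decimal
(half-away-from-zero) — rounding never feeds back into computation.
No multiple-testing adjustment is applied; each p-value and interval
stands on its own at the 0.05 / 95% level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _version
from .classify import ClassifiedCohort, classify_and_derive
from .cohort import Cohort
from .interaction import STATUS_OK, interaction_analysis
from .logistic import DEFAULT_ADJUSTMENT, SeparationError, estimate_or

__all__ = [
    "round_half_away",
    "descriptive_table",
    "run_table2",
    "run_table3",
    "RunReport",
    "run_all",
    "write_report",
    "TABLE2_EXPOSURES",
    "TABLE3_PAIRS",
]

TABLE2_EXPOSURES = (
    "phd",
    "paternal_history",
    "maternal_history",
    "biparental",
    "family_history",
)

#: (exposure A, exposure B) pairs of the interaction table; B is the
#: family-history exposure throughout.
TABLE3_PAIRS = (
    ("bmi_gt25", "phd"),
    ("bmi_gt30", "phd"),
    ("leisure_inactive", "phd"),
    ("work_inactive", "phd"),
    ("current_smoker", "phd"),
)

#: alternative adiposity dichotomisations (sex-specific upper decile)
TABLE3_P90_PAIRS = (
    ("high_sad", "phd"),
    ("high_waist", "phd"),
    ("high_whr", "phd"),
    ("high_bmi_p90", "phd"),
)

_CATEGORICAL_VARS = (
    ("phd", "Parental history of diabetes"),
    ("maternal_history", "Maternal history of diabetes"),
    ("paternal_history", "Paternal history of diabetes"),
    ("current_smoker", "Current smokers"),
    ("ex_smoker", "Ex-smokers"),
    ("leisure_inactive", "Physical inactivity, leisure time"),
    ("work_inactive", "Physical inactivity at work"),
    ("bmi_gt25", "BMI>25"),
    ("bmi_gt30", "BMI>30"),
)
# approximately normal: mean +/- SD with Student's t-test
_NORMAL_VARS = (
    ("bmi", "BMI (kg/m2)"),
    ("whr", "Waist-to-hip ratio"),
    ("waist", "Waist circumference (cm)"),
    ("ldl", "LDL (mmol/l)"),
    ("systolic_bp", "Systolic blood pressure (mmHg)"),
    ("diastolic_bp", "Diastolic blood pressure (mmHg)"),
)
# skewed: median (IQR) with Kruskal-Wallis
_SKEWED_VARS = (
    ("fasting_glucose", "Glucose (mmol/l)"),
    ("sad", "Sagittal abdominal diameter (cm)"),
    ("insulin", "Insulin (uU/ml)"),
    ("hdl", "HDL (mmol/l)"),
    ("triglycerides", "Triglycerides (mmol/l)"),
)


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (report layer only)."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return float("nan")
    factor = 10.0 ** ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def _var_series(study: ClassifiedCohort, var: str) -> Optional[pd.Series]:
    if var in study.panel.columns:
        return study.panel[var]
    if var in study.df.columns:
        return study.df[var]
    return None


def descriptive_table(study: ClassifiedCohort) -> pd.DataFrame:
    """Characteristics by outcome class within sex, vs the reference class.

    Categorical variables: percentage and chi-square p; approximately
    normal continuous: mean +/- SD and Student's t-test p; skewed
    continuous: median (IQR) and Kruskal-Wallis p.  Missing counts are
    reported per cell.  Empty strata yield rows marked unavailable.
    """
    rows = []
    out = study.outcome.astype(str)
    for sex in ("male", "female"):
        sex_mask = study.df["sex"] == sex
        ref_mask = sex_mask & (out == "reference")
        for cls in ("diabetes", "prediabetes"):
            cls_mask = sex_mask & (out == cls)
            for var, label, kind in (
                [(v, l, "categorical") for v, l in _CATEGORICAL_VARS]
                + [(v, l, "normal") for v, l in _NORMAL_VARS]
                + [(v, l, "skewed") for v, l in _SKEWED_VARS]
            ):
                s = _var_series(study, var)
                if s is None:
                    continue
                if var == "maternal_history":
                    elig = study.panel["maternal_eligible"].fillna(False).astype(bool)
                elif var == "paternal_history":
                    elig = study.panel["paternal_eligible"].fillna(False).astype(bool)
                else:
                    elig = pd.Series(True, index=s.index)
                a = s[cls_mask & elig]
                b = s[ref_mask & elig]
                rows.append(
                    _describe_one(sex, cls, var, label, kind, a, b)
                )
    return pd.DataFrame(rows)


def _describe_one(sex, cls, var, label, kind, a: pd.Series, b: pd.Series) -> dict:
    row = {
        "sex": sex,
        "outcome": cls,
        "variable": var,
        "label": label,
        "kind": kind,
        "n_missing_class": int(a.isna().sum()),
        "n_missing_reference": int(b.isna().sum()),
        "summary_class": "",
        "summary_reference": "",
        "p_vs_reference": float("nan"),
        "note": "",
    }
    a = a.dropna()
    b = b.dropna()
    if len(a) == 0 or len(b) == 0:
        row["note"] = "empty stratum"
        return row
    if kind == "categorical":
        av = a.astype(bool)
        bv = b.astype(bool)
        row["summary_class"] = f"{100 * av.mean():.1f}%"
        row["summary_reference"] = f"{100 * bv.mean():.1f}%"
        table = np.array(
            [[av.sum(), len(av) - av.sum()], [bv.sum(), len(bv) - bv.sum()]],
            dtype=float,
        )
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            row["note"] = "degenerate 2x2 table"
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            row["p_vs_reference"] = float(p)
    elif kind == "normal":
        av = a.to_numpy(dtype=float)
        bv = b.to_numpy(dtype=float)
        row["summary_class"] = f"{av.mean():.1f}±{av.std(ddof=1):.1f}"
        row["summary_reference"] = f"{bv.mean():.1f}±{bv.std(ddof=1):.1f}"
        if len(av) > 1 and len(bv) > 1:
            _, p = stats.ttest_ind(av, bv)
            row["p_vs_reference"] = float(p)
    else:
        av = a.to_numpy(dtype=float)
        bv = b.to_numpy(dtype=float)
        qa = np.percentile(av, [25, 50, 75])
        qb = np.percentile(bv, [25, 50, 75])
        row["summary_class"] = f"{qa[1]:.1f} ({qa[0]:.1f}-{qa[2]:.1f})"
        row["summary_reference"] = f"{qb[1]:.1f} ({qb[0]:.1f}-{qb[2]:.1f})"
        try:
            _, p = stats.kruskal(av, bv)
            row["p_vs_reference"] = float(p)
        except ValueError:  # all values identical
            row["p_vs_reference"] = 1.0
    return row


def run_table2(
    study: ClassifiedCohort,
    covariates: Sequence[str] = DEFAULT_ADJUSTMENT,
) -> pd.DataFrame:
    """Crude and adjusted prevalence odds ratios for the family-history
    exposures, per outcome and stratum.

    Strata are men, women, and both sexes (the pooled adjusted model
    carries an additional sex indicator).  Rows whose model fails
    (zero cell, separation) are flagged and the run continues.
    """
    rows = []
    for target in ("diabetes", "prediabetes"):
        for exposure in TABLE2_EXPOSURES:
            for stratum in ("male", "female", "both"):
                sex = None if stratum == "both" else stratum
                for model, covs in (
                    ("crude", ()),
                    ("adjusted", tuple(covariates) + (("sex",) if stratum == "both" else ())),
                ):
                    row = {
                        "outcome": target,
                        "exposure": exposure,
                        "stratum": stratum,
                        "model": model,
                        "or": float("nan"),
                        "ci_low": float("nan"),
                        "ci_high": float("nan"),
                        "beta": float("nan"),
                        "se": float("nan"),
                        "n_used": 0,
                        "n_dropped": 0,
                        "note": "",
                    }
                    try:
                        res = estimate_or(
                            study, exposure, target=target, covariates=covs, sex=sex
                        )
                        row.update(
                            {
                                "or": res.or_,
                                "ci_low": res.ci_low,
                                "ci_high": res.ci_high,
                                "beta": res.beta,
                                "se": res.se,
                                "n_used": res.n_used,
                                "n_dropped": res.n_dropped,
                            }
                        )
                    except (SeparationError, ValueError, np.linalg.LinAlgError) as e:
                        row["note"] = f"not estimable: {e}"
                    rows.append(row)
    return pd.DataFrame(rows)


def run_table3(
    study: ClassifiedCohort,
    pairs: Sequence[tuple] = TABLE3_PAIRS,
    target: str = "diabetes",
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Additive-interaction table: per sex and exposure pair, the four
    cells' exposed-case counts, the three joint odds ratios and the
    synergy index with its delta-method interval.

    Failed rows (zero cells, separation) are flagged; the run
    continues.
    """
    rows = []
    for sex in ("male", "female"):
        for exp_a, exp_b in pairs:
            base = {
                "sex": sex,
                "exposure_a": exp_a,
                "exposure_b": exp_b,
                "outcome": target,
            }
            try:
                res = interaction_analysis(
                    study, exp_a, exp_b, target=target,
                    covariates=covariates, sex=sex,
                )
            except (SeparationError, ValueError, np.linalg.LinAlgError) as e:
                rows.append(
                    {**base, "cell": "all", "note": f"not estimable: {e}"}
                )
                continue
            for cell, orres in (
                ("reference", None),
                ("a_only", res.or10),
                ("b_only", res.or01),
                ("both", res.or11),
            ):
                row = {
                    **base,
                    "cell": cell,
                    "cases": res.cell_cases[
                        {"reference": "ref", "a_only": "a_only",
                         "b_only": "b_only", "both": "both"}[cell]
                    ],
                    "or": 1.0 if orres is None else orres.or_,
                    "ci_low": float("nan") if orres is None else orres.ci_low,
                    "ci_high": float("nan") if orres is None else orres.ci_high,
                    "s": float("nan"),
                    "s_ci_low": float("nan"),
                    "s_ci_high": float("nan"),
                    "status": "",
                    "note": "",
                }
                if cell == "both":
                    row["status"] = res.status
                    if res.status == STATUS_OK:
                        row["s"] = res.s
                        row["s_ci_low"], row["s_ci_high"] = res.s_ci
                zero = [k for k, v in res.cell_cases.items() if v == 0]
                if zero:
                    row["note"] = f"zero-case cells: {','.join(zero)}"
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RunReport:
    """Provenance, per-stage counts and the three report tables."""

    provenance: str
    seed: Optional[int]
    version: str
    counts: dict
    descriptive: Optional[pd.DataFrame] = None
    table2: Optional[pd.DataFrame] = None
    table3: Optional[pd.DataFrame] = None
    cutoffs: dict = field(default_factory=dict)
    config_echo: dict = field(default_factory=dict)

    def reconcile(self) -> bool:
        """classified + excluded must equal the input size."""
        c = self.counts
        classified = (
            c.get("diabetes", 0) + c.get("prediabetes", 0) + c.get("reference", 0)
        )
        return classified + c.get("excluded", 0) == c.get("n_input", -1)


def run_all(
    cohort: Cohort,
    tables: Sequence[str] = ("descriptive", "table2", "table3"),
    seed: Optional[int] = None,
    config_echo: Optional[dict] = None,
) -> RunReport:
    """Classify, derive exposures and produce the requested tables."""
    study = classify_and_derive(cohort)
    counts = {"n_input": len(cohort), **study.counts()}
    report = RunReport(
        provenance=cohort.provenance,
        seed=seed,
        version=_version,
        counts=counts,
        cutoffs=study.cutoffs.to_dict(),
        config_echo=config_echo or {},
    )
    if "descriptive" in tables:
        report.descriptive = descriptive_table(study)
    if "table2" in tables:
        report.table2 = run_table2(study)
    if "table3" in tables:
        report.table3 = run_table3(study)
    return report


def _rounded(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: round_half_away(v, 1))
    return out


def write_report(report: RunReport, outdir: str | Path) -> Path:
    """Write full-precision JSON plus rounded one-decimal TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "provenance": report.provenance,
        "seed": report.seed,
        "version": report.version,
        "counts": report.counts,
        "cutoffs": report.cutoffs,
        "config_echo": report.config_echo,
    }
    for name in ("descriptive", "table2", "table3"):
        df = getattr(report, name)
        if df is not None:
            payload[name] = df.to_dict(orient="records")
            _rounded(df).to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=1, default=_json_default)
    return outdir / "report.json"


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, float) and np.isnan(o):
        return None
    return str(o)
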