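"""Additive interaction between two dichotomous exposures.

Two exposures A and B define four cells; a single logistic model with
three joint-exposure indicators (A only, B only, both) against the
doubly-unexposed reference yields the three odds ratios OR10, OR01 and
OR11.  Departure from additivity of odds-ratio effects is summarised
by:

* the synergy index  S = (OR11 - 1) / ((OR10 - 1) + (OR01 - 1)),
  with S > 1 indicating synergy and S < 1 antagonism;
* RERI = OR11 - OR10 - OR01 + 1, the relative excess risk due to
  interaction (0 under exact additivity);
* AP = RERI / OR11, the attributable proportion due to interaction.

Confidence intervals use the delta method on the fitted coefficient
covariance: for S on the log scale (interval back-transformed by exp),
for RERI and AP on their own scales.  A seeded percentile bootstrap is
available as a cross-check for sparse double-exposure cells, where the
normal approximation is least trustworthy and the intervals are wide.

Degenerate cases carry a status flag instead of a number: when
OR11 <= 1 the numerator of S is non-positive and no synergy index is
reported (``no_result``); when OR11 > 1 but (OR10-1)+(OR01-1) <= 0 the
denominator changes sign and S is undefined
(``undefined_antagonism_denominator``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import ClassifiedCohort, OutcomeClass
from .logistic import (
    Z95,
    FitResult,
    ORResult,
    SeparationError,
    _as_float,
    build_design,
    fit_logistic,
)

__all__ = [
    "STATUS_OK",
    "STATUS_NO_RESULT",
    "STATUS_UNDEFINED_DENOM",
    "joint_indicator_coding",
    "synergy_index_from_ors",
    "reri_ap_from_ors",
    "InteractionResult",
    "interaction_analysis",
]

STATUS_OK = "ok"
STATUS_NO_RESULT = "no_result"
STATUS_UNDEFINED_DENOM = "undefined_antagonism_denominator"


def joint_indicator_coding(a, b) -> pd.DataFrame:
    """Three indicators (i10, i01, i11) from two 0/1 exposures.

    The doubly-unexposed cell is the all-zero reference; in every other
    cell exactly one indicator is 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return pd.DataFrame(
        {
            "i10": (a == 1) & (b == 0),
            "i01": (a == 0) & (b == 1),
            "i11": (a == 1) & (b == 1),
        }
    ).astype(float)


def synergy_index_from_ors(
    or11: float, or10: float, or01: float
) -> tuple[float, str]:
    """Synergy index from three odds ratios; (value, status).

    The value is NaN unless the status is ``ok``.
    """
    if min(or11, or10, or01) <= 0:
        raise ValueError("odds ratios must be positive")
    if or11 <= 1.0:
        return float("nan"), STATUS_NO_RESULT
    denom = (or10 - 1.0) + (or01 - 1.0)
    if denom <= 0.0:
        return float("nan"), STATUS_UNDEFINED_DENOM
    return (or11 - 1.0) / denom, STATUS_OK


def reri_ap_from_ors(or11: float, or10: float, or01: float) -> tuple[float, float]:
    """RERI and AP from three odds ratios."""
    if min(or11, or10, or01) <= 0:
        raise ValueError("odds ratios must be positive")
    reri = or11 - or10 - or01 + 1.0
    return reri, reri / or11


@dataclass
class InteractionResult:
    """Joint-exposure odds ratios and additive-interaction measures."""

    or10: ORResult
    or01: ORResult
    or11: ORResult
    s: float
    s_ci: tuple
    reri: float
    reri_ci: tuple
    ap: float
    ap_ci: tuple
    status: str
    cell_cases: dict  # cases per exposure cell: ref, a_only, b_only, both
    cell_totals: dict
    n_used: int
    n_dropped: int
    fit: FitResult
    s_ci_bootstrap: Optional[tuple] = None
    exposure_a: str = ""
    exposure_b: str = ""


def _delta_cis(beta3: np.ndarray, cov3: np.ndarray):
    """Delta-method 95% CIs for ln S, RERI and AP.

    ``beta3`` = (b10, b01, b11) and ``cov3`` its covariance block.
    Returns (s_ci, reri_ci, ap_ci, se_lnS); s_ci is (nan, nan) when S
    is degenerate.
    """
    e10, e01, e11 = np.exp(beta3)
    reri = e11 - e10 - e01 + 1.0
    ap = reri / e11

    # RERI: gradient of e11 - e10 - e01 + 1
    g_reri = np.array([-e10, -e01, e11])
    se_reri = float(np.sqrt(g_reri @ cov3 @ g_reri))
    reri_ci = (reri - Z95 * se_reri, reri + Z95 * se_reri)

    # AP = 1 - (e10 + e01 - 1)/e11
    g_ap = np.array([-e10 / e11, -e01 / e11, (e10 + e01 - 1.0) / e11])
    se_ap = float(np.sqrt(g_ap @ cov3 @ g_ap))
    ap_ci = (ap - Z95 * se_ap, ap + Z95 * se_ap)

    num = e11 - 1.0
    den = (e10 - 1.0) + (e01 - 1.0)
    if num <= 0 or den <= 0:
        return (float("nan"), float("nan")), reri_ci, ap_ci, float("nan")
    # ln S = ln(e11 - 1) - ln((e10 - 1) + (e01 - 1))
    g_lnS = np.array([-e10 / den, -e01 / den, e11 / num])
    se_lnS = float(np.sqrt(g_lnS @ cov3 @ g_lnS))
    lnS = np.log(num / den)
    s_ci = (float(np.exp(lnS - Z95 * se_lnS)), float(np.exp(lnS + Z95 * se_lnS)))
    return s_ci, reri_ci, ap_ci, se_lnS


def interaction_analysis(
    study: ClassifiedCohort,
    exposure_a: str,
    exposure_b: str,
    target: str = "diabetes",
    covariates: Sequence[str] = (),
    sex: Optional[str] = None,
    bootstrap: int = 0,
    seed: Optional[int] = None,
) -> InteractionResult:
    """Fit the joint-exposure model and compute S, RERI and AP.

    Analysis set: ``target`` cases plus the reference outcome class,
    restricted to records with both exposures (and all covariates)
    non-missing; dropped records are counted.  ``bootstrap > 0`` adds a
    seeded percentile bootstrap interval for S.
    """
    out = study.outcome.astype(str)
    keep = out.isin([target, OutcomeClass.reference.value])
    if sex is not None:
        keep &= study.df["sex"] == sex
    n_candidates = int(keep.sum())

    frame = pd.DataFrame(
        {
            "y": (out == target).astype(float),
            "a": _as_float(study.panel[exposure_a]),
            "b": _as_float(study.panel[exposure_b]),
        }
    )
    for cov in covariates:
        if cov == "sex":
            frame["sex"] = study.df["sex"]
        elif cov in study.panel.columns:
            frame[cov] = _as_float(study.panel[cov])
        else:
            frame[cov] = _as_float(study.df[cov])
    frame = frame[keep].dropna()
    n_dropped = n_candidates - len(frame)

    ind = joint_indicator_coding(frame["a"], frame["b"])
    ind.index = frame.index
    model = pd.concat([frame, ind], axis=1)
    terms = ["i10", "i01", "i11"] + list(covariates)

    y = model["y"].to_numpy()
    a = model["a"].to_numpy()
    b = model["b"].to_numpy()
    cells = {
        "ref": (a == 0) & (b == 0),
        "a_only": (a == 1) & (b == 0),
        "b_only": (a == 0) & (b == 1),
        "both": (a == 1) & (b == 1),
    }
    cell_cases = {k: int(y[m].sum()) for k, m in cells.items()}
    cell_totals = {k: int(m.sum()) for k, m in cells.items()}

    X = build_design(model, terms)
    fit = fit_logistic(X, y)
    idx = slice(1, 4)  # i10, i01, i11 follow the intercept
    beta3 = fit.beta[idx]
    cov3 = fit.cov[idx, idx]
    se3 = np.sqrt(np.diag(cov3))

    def _orres(j: int, term: str, ncase_key: str) -> ORResult:
        return ORResult.from_beta(
            beta3[j], se3[j], n_used=len(model), term=term,
            counts=(cell_cases[ncase_key], cell_totals[ncase_key] - cell_cases[ncase_key],
                    cell_cases["ref"], cell_totals["ref"] - cell_cases["ref"]),
        )

    or10 = _orres(0, f"{exposure_a} only", "a_only")
    or01 = _orres(1, f"{exposure_b} only", "b_only")
    or11 = _orres(2, f"{exposure_a} and {exposure_b}", "both")

    s, status = synergy_index_from_ors(or11.or_, or10.or_, or01.or_)
    reri, ap = reri_ap_from_ors(or11.or_, or10.or_, or01.or_)
    s_ci, reri_ci, ap_ci, _ = _delta_cis(beta3, cov3)

    boot_ci = None
    if bootstrap > 0:
        boot_ci = _bootstrap_s(model, terms, bootstrap, seed)

    return InteractionResult(
        or10=or10,
        or01=or01,
        or11=or11,
        s=s,
        s_ci=s_ci,
        reri=reri,
        reri_ci=reri_ci,
        ap=ap,
        ap_ci=ap_ci,
        status=status,
        cell_cases=cell_cases,
        cell_totals=cell_totals,
        n_used=len(model),
        n_dropped=n_dropped,
        fit=fit,
        s_ci_bootstrap=boot_ci,
        exposure_a=exposure_a,
        exposure_b=exposure_b,
    )


def _bootstrap_s(
    model: pd.DataFrame, terms: Sequence[str], n_boot: int, seed: Optional[int]
) -> tuple:
    """Percentile bootstrap interval for S (resampling records)."""
    rng = np.random.default_rng(seed)
    y_all = model["y"].to_numpy()
    X_all = build_design(model, terms)
    n = len(model)
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = y_all[idx]
        if yb.min() == yb.max():
            continue
        try:
            fit = fit_logistic(X_all[idx], yb)
        except (SeparationError, np.linalg.LinAlgError):
            continue
        e10, e01, e11 = np.exp(fit.beta[1:4])
        s, status = synergy_index_from_ors(e11, e10, e01)
        if status == STATUS_OK:
            stats.append(s)
    if len(stats) < max(20, n_boot // 4):
        return (float("nan"), float("nan"))
    return tuple(np.percentile(stats, [2.5, 97.5]))
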