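"""Maximum-likelihood logistic regression and prevalence odds ratios.

The fitter is plain Newton-Raphson / iteratively reweighted least
squares (IRLS) with the coefficient covariance taken as the inverse
observed information at the MLE; for a logistic model the observed and
expected information coincide.  Complete or quasi-complete separation
is detected by coefficient divergence and raised as an explicit error
rather than returned as an absurdly large odds ratio.

For a single binary exposure the crude fit has a closed form: the
log-odds-ratio is the log cross-product ratio of the 2x2 table and its
standard error is Woolf's ``sqrt(1/a + 1/b + 1/c + 1/d)``.  That closed
form is exposed as :func:`odds_ratio_2x2` and doubles as an independent
oracle for the iterative fitter.

Cohort-level estimation (:func:`estimate_or`) contrasts one outcome
class (diabetes or prediabetes) against the reference class only;
records in the other outcome class, excluded records, analysis-specific
ineligible records (e.g. paternal history reported, in a
maternal-history analysis) and records with any missing model variable
are dropped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .classify import ClassifiedCohort, OutcomeClass

__all__ = [
    "Z95",
    "SeparationError",
    "FitResult",
    "ORResult",
    "fit_logistic",
    "odds_ratio_2x2",
    "estimate_or",
    "build_design",
    "DEFAULT_ADJUSTMENT",
]

#: two-sided 95% normal quantile
Z95 = 1.959964

#: Adjustment terms used by the "adjusted" models: smoking as two
#: dummies (never-smoker reference), the two inactivity indicators and
#: BMI as a continuous term.
DEFAULT_ADJUSTMENT = (
    "current_smoker",
    "ex_smoker",
    "leisure_inactive",
    "work_inactive",
    "bmi",
)


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


@dataclass
class FitResult:
    beta: np.ndarray  # coefficients, log-odds scale
    cov: np.ndarray  # inverse information at the MLE
    loglik: float
    converged: bool
    n_used: int
    n_iter: int

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


@dataclass
class ORResult:
    """One exposure's odds ratio with its Wald interval.

    ``counts`` holds (cases_exposed, noncases_exposed, cases_unexposed,
    noncases_unexposed) when the model has a single binary exposure.
    """

    or_: float
    ci_low: float
    ci_high: float
    beta: float
    se: float
    n_used: int = 0
    n_dropped: int = 0
    counts: Optional[tuple] = None
    term: str = ""

    @classmethod
    def from_beta(cls, beta: float, se: float, **kw) -> "ORResult":
        return cls(
            or_=float(np.exp(beta)),
            ci_low=float(np.exp(beta - Z95 * se)),
            ci_high=float(np.exp(beta + Z95 * se)),
            beta=float(beta),
            se=float(se),
            **kw,
        )


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1 + e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
    beta_cap: float = 15.0,
) -> FitResult:
    """Fit a logistic model by IRLS (Newton-Raphson).

    ``X`` is the n x p design including the intercept column; ``y`` is
    0/1.  Convergence: max absolute score below ``score_tol`` or
    relative log-likelihood change below ``ll_tol``; at most
    ``max_iter`` iterations.  Any coefficient exceeding ``beta_cap`` in
    absolute value raises :class:`SeparationError`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")

    beta = np.zeros(p)
    ll = _loglik(X, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as e:
            raise SeparationError(f"singular information matrix: {e}") from e
        # step-halving keeps Newton monotone on awkward fixtures
        new_beta = beta + step
        new_ll = _loglik(X, y, new_beta)
        halvings = 0
        while new_ll < ll and halvings < 20:
            step *= 0.5
            new_beta = beta + step
            new_ll = _loglik(X, y, new_beta)
            halvings += 1
        beta, prev_ll, ll = new_beta, ll, new_ll
        if np.max(np.abs(beta)) > beta_cap:
            raise SeparationError(
                "coefficient diverged beyond "
                f"{beta_cap}: complete or quasi-complete separation"
            )
        if abs(ll - prev_ll) < ll_tol * (abs(prev_ll) + 1e-300):
            converged = True
            break

    mu = expit(X @ beta)
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    return FitResult(
        beta=beta, cov=cov, loglik=ll, converged=converged, n_used=n, n_iter=it
    )


def odds_ratio_2x2(a: float, b: float, c: float, d: float) -> ORResult:
    """Closed-form odds ratio from a 2x2 table.

    ``a``/``b`` are exposed cases/non-cases; ``c``/``d`` unexposed.
    OR = ad/(bc); Woolf SE on the log scale; 95% Wald interval.  A zero
    cell raises — choose a coarser exposure or report the cell instead
    of applying a silent continuity correction.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (cells == 0).any():
        raise ValueError(
            "zero cell in 2x2 table: the odds ratio is undefined; no "
            "automatic continuity correction is applied"
        )
    beta = float(np.log(a * d / (b * c)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return ORResult.from_beta(beta, se, counts=(int(a), int(b), int(c), int(d)),
                              n_used=int(cells.sum()))


def build_design(
    frame: pd.DataFrame, terms: Sequence[str]
) -> np.ndarray:
    """Intercept + the named columns as a float design matrix.

    Boolean (nullable) columns become 0/1; the pseudo-term ``"sex"``
    is an indicator for female.
    """
    cols = [np.ones(len(frame))]
    for t in terms:
        v = frame[t]
        if t == "sex":
            cols.append((v == "female").to_numpy(dtype=float))
        else:
            cols.append(v.to_numpy(dtype=float))
    return np.column_stack(cols)


def _as_float(s: pd.Series) -> np.ndarray:
    """Nullable boolean/integer/float series -> float64 with NaN."""
    return pd.Series(s).astype("Float64").to_numpy(dtype="float64", na_value=np.nan)


def _analysis_frame(
    study: ClassifiedCohort,
    exposure: str,
    target: str,
    covariates: Sequence[str],
    sex: Optional[str],
) -> tuple[pd.DataFrame, int]:
    """Complete-case analysis frame: y, exposure, covariates.

    Returns the frame and the number of candidate records dropped
    (other-class, ineligible, or missing model variables).
    """
    if target not in ("diabetes", "prediabetes"):
        raise ValueError(f"target must be diabetes or prediabetes, got {target!r}")
    out = study.outcome.astype(str)
    keep = out.isin([target, OutcomeClass.reference.value])
    if sex is not None:
        keep &= study.df["sex"] == sex
    n_candidates = int(keep.sum())

    elig_col = {"maternal_history": "maternal_eligible",
                "paternal_history": "paternal_eligible"}.get(exposure)
    if elig_col is not None:
        keep &= study.panel[elig_col].fillna(False).to_numpy(dtype=bool)

    frame = pd.DataFrame({"y": (out == target).astype(float)})
    frame["exposure"] = _as_float(study.panel[exposure])
    for cov in covariates:
        if cov == "sex":
            frame["sex"] = study.df["sex"]
        elif cov in study.panel.columns:
            frame[cov] = _as_float(study.panel[cov])
        else:
            frame[cov] = _as_float(study.df[cov])
    frame = frame[keep]
    frame = frame.dropna()
    return frame, n_candidates - len(frame)


def estimate_or(
    study: ClassifiedCohort,
    exposure: str,
    target: str = "diabetes",
    covariates: Sequence[str] = (),
    sex: Optional[str] = None,
) -> ORResult:
    """Prevalence odds ratio for one exposure (crude or adjusted).

    ``covariates=()`` gives the crude estimate, which coincides exactly
    with the closed-form 2x2 odds ratio on the same analysis set.  Pass
    :data:`DEFAULT_ADJUSTMENT` (optionally plus ``"sex"``) for the
    adjusted models.
    """
    frame, n_dropped = _analysis_frame(study, exposure, target, covariates, sex)
    terms = ["exposure"] + [c for c in covariates]
    X = build_design(frame, terms)
    y = frame["y"].to_numpy()
    fit = fit_logistic(X, y)
    counts = None
    e = frame["exposure"].to_numpy()
    if set(np.unique(e)) <= {0.0, 1.0}:
        counts = (
            int(((e == 1) & (y == 1)).sum()),
            int(((e == 1) & (y == 0)).sum()),
            int(((e == 0) & (y == 1)).sum()),
            int(((e == 0) & (y == 0)).sum()),
        )
    return ORResult.from_beta(
        fit.beta[1],
        float(np.sqrt(fit.cov[1, 1])),
        n_used=len(frame),
        n_dropped=n_dropped,
        counts=counts,
        term=exposure,
    )
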