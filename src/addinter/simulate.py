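"""Seeded generator of synthetic cross-sectional cohorts.

The generator emulates the statistical structure the downstream
analysis assumes: a cohort of 60-year-old men and women with binary
family-history and lifestyle exposures, a three-class outcome
(diabetes / prediabetes / reference), fasting glucose drawn within the
band implied by the outcome class, and anthropometrics driven by a
shared latent adiposity factor.  It exists so that every pipeline stage
is testable against a known ground truth.

Outcome model
-------------
Records are drawn independently.  Per sex, a designated exposure pair
(by default obesity BMI>30 and parental history of diabetes) defines
four cells; outcome classes follow a baseline-category logit with the
reference class as baseline:

    P(class) ∝ {1, exp(a_d + bd_cell), exp(a_p + bp_cell)}

where the cell effects ``bd`` are the configured log odds ratios
(OR10, OR01, OR11) of diabetes versus reference.  Because the analysis
contrasts each outcome against the reference class only, the fitted
odds ratios estimate exactly the configured ones.  The intercepts
``a_d, a_p`` are calibrated numerically so that the marginal class
prevalences hit their per-sex targets.

Glucose is sampled from a log-normal matched to a per-class median and
interquartile range, truncated to the class band (diabetes identified
by glucose: >= 7.0 mmol/l; prediabetes: [6.1, 6.9]; reference:
< 6.1), so re-classifying a generated record always reproduces its
latent class.  A configurable fraction of self-reported diabetes cases
is "non-validated": glucose below 7.0 and no antidiabetic medication.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import root
from scipy.special import expit, ndtr, ndtri

from .cohort import Cohort
from .interaction import synergy_index_from_ors

__all__ = [
    "ConfigError",
    "SexParams",
    "CohortConfig",
    "paper_default_config",
    "generate_cohort",
    "true_interaction",
    "TrueInteraction",
]

_Z75 = 0.6744897501960817  # standard-normal 75% quantile


class ConfigError(ValueError):
    """The generator configuration is invalid or infeasible."""


@dataclass(frozen=True)
class SexParams:
    """Per-sex generator parameters.

    Prevalences are marginal probabilities; odds ratios refer to the
    designated exposure pair A = obesity (BMI>30), B = parental history
    (diabetes versus the reference class, per cell against the doubly
    unexposed).
    """

    # family history
    p_mother: float
    p_father: float
    p_sibling_given_phd: float
    p_sibling_no_phd: float
    # smoking: current/ex/never; optional dependence of current smoking
    # on parental history as an odds multiplier
    p_current_smoker: float
    p_ex_smoker: float
    smoking_phd_or: float
    # four-level activity items (level 1 = inactive/sedentary)
    leisure_dist: tuple
    work_dist: tuple
    # anthropometrics (means/SDs); BMI is the primary adiposity draw,
    # the others load on it with correlation ``adiposity_corr``
    height_mean: float
    height_sd: float
    bmi_mean: float
    bmi_sd: float
    waist_mean: float
    waist_sd: float
    hip_mean: float
    hip_sd: float
    sad_mean: float
    sad_sd: float
    adiposity_corr: float
    # outcome model
    p_diabetes: float
    p_prediabetes: float
    or10_diabetes: float  # obesity only
    or01_diabetes: float  # parental history only
    or11_diabetes: float  # both
    or_obese_prediabetes: float
    or_phd_prediabetes: float
    # diabetes-case reporting structure
    p_selfreport: float
    p_med_given_selfreport: float
    p_nonvalidated: float
    # glucose distributions: (median, q1, q3) per class, mmol/l
    glucose_diabetes: tuple
    glucose_prediabetes: tuple
    glucose_reference: tuple


@dataclass(frozen=True)
class CohortConfig:
    n: int
    male_frac: float
    excluded_frac: float
    men: SexParams
    women: SexParams
    missing_rates: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        for name, v in (("male_frac", self.male_frac),
                        ("excluded_frac", self.excluded_frac)):
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for sexname, sp in (("men", self.men), ("women", self.women)):
            probs = {
                "p_mother": sp.p_mother, "p_father": sp.p_father,
                "p_sibling_given_phd": sp.p_sibling_given_phd,
                "p_sibling_no_phd": sp.p_sibling_no_phd,
                "p_current_smoker": sp.p_current_smoker,
                "p_ex_smoker": sp.p_ex_smoker,
                "p_diabetes": sp.p_diabetes, "p_prediabetes": sp.p_prediabetes,
                "p_selfreport": sp.p_selfreport,
                "p_med_given_selfreport": sp.p_med_given_selfreport,
                "p_nonvalidated": sp.p_nonvalidated,
            }
            for k, v in probs.items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"{sexname}.{k} must be in [0, 1]")
            if sp.p_current_smoker + sp.p_ex_smoker > 1.0:
                raise ConfigError(f"{sexname}: smoking category probabilities exceed 1")
            if sp.p_diabetes + sp.p_prediabetes >= 1.0:
                raise ConfigError(f"{sexname}: outcome prevalences must sum below 1")
            for dname, dist in (("leisure_dist", sp.leisure_dist),
                                ("work_dist", sp.work_dist)):
                if len(dist) != 4 or abs(sum(dist) - 1.0) > 1e-9 or min(dist) < 0:
                    raise ConfigError(f"{sexname}.{dname} must be 4 probabilities summing to 1")
            for oname in ("or10_diabetes", "or01_diabetes", "or11_diabetes",
                          "or_obese_prediabetes", "or_phd_prediabetes"):
                if getattr(sp, oname) <= 0:
                    raise ConfigError(f"{sexname}.{oname} must be positive")
        for k, v in self.missing_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"missing_rates[{k!r}] must be in [0, 1]")

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        men = d.pop("men")
        women = d.pop("women")
        def _sp(x):
            x = dict(x)
            for k in ("leisure_dist", "work_dist", "glucose_diabetes",
                      "glucose_prediabetes", "glucose_reference"):
                x[k] = tuple(x[k])
            return SexParams(**x)
        return cls(men=_sp(men), women=_sp(women), **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _plain(obj):
    """Recursively convert tuples/numpy scalars for YAML round-trips."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


class TrueInteraction(NamedTuple):
    or10: float
    or01: float
    or11: float
    s: float
    status: str


def true_interaction(config: CohortConfig, sex: str = "male") -> TrueInteraction:
    """The generator's configured ground truth for the designated pair."""
    sp = config.men if sex == "male" else config.women
    s, status = synergy_index_from_ors(
        sp.or11_diabetes, sp.or10_diabetes, sp.or01_diabetes
    )
    return TrueInteraction(
        or10=sp.or10_diabetes, or01=sp.or01_diabetes, or11=sp.or11_diabetes,
        s=s, status=status,
    )


def paper_default_config() -> CohortConfig:
    """Default configuration: a 60-year-old urban cohort, n = 4232.

    Prevalence and distribution defaults emulate the reference study
    conditions: ~48/52 male/female split; diabetes in ~10.1% of men and
    ~5.2% of women, prediabetes in ~11.0% and ~5.3%; parental-history
    prevalence ~13% (men) and ~16% (women); current smoking ~21%;
    obesity ~17-18%; Table-style glucose medians per class.  The
    designated interaction truth is the obesity-by-parental-history
    odds-ratio triplet (3.4, 2.0, 9.1) in men and (4.4, 1.6, 4.0) in
    women.
    """
    men = SexParams(
        p_mother=0.082, p_father=0.052,
        p_sibling_given_phd=0.174, p_sibling_no_phd=0.062,
        p_current_smoker=0.207, p_ex_smoker=0.455, smoking_phd_or=0.684,
        leisure_dist=(0.107, 0.40, 0.31, 0.183),
        work_dist=(0.32, 0.26, 0.24, 0.18),
        height_mean=178.0, height_sd=6.5,
        bmi_mean=26.6, bmi_sd=3.55,
        waist_mean=97.5, waist_sd=10.2,
        hip_mean=103.0, hip_sd=6.5,
        sad_mean=21.3, sad_sd=2.4,
        adiposity_corr=0.8,
        p_diabetes=0.1006, p_prediabetes=0.1099,
        or10_diabetes=3.4, or01_diabetes=2.0, or11_diabetes=9.1,
        or_obese_prediabetes=2.66, or_phd_prediabetes=1.6,
        p_selfreport=0.546, p_med_given_selfreport=0.78, p_nonvalidated=0.03,
        glucose_diabetes=(8.7, 7.4, 11.1),
        glucose_prediabetes=(6.3, 6.2, 6.6),
        glucose_reference=(5.2, 4.9, 5.5),
    )
    women = SexParams(
        p_mother=0.115, p_father=0.055,
        p_sibling_given_phd=0.137, p_sibling_no_phd=0.036,
        p_current_smoker=0.218, p_ex_smoker=0.317, smoking_phd_or=1.0,
        leisure_dist=(0.118, 0.45, 0.27, 0.162),
        work_dist=(0.33, 0.26, 0.24, 0.17),
        height_mean=164.5, height_sd=6.0,
        bmi_mean=26.3, bmi_sd=4.05,
        waist_mean=87.0, waist_sd=11.5,
        hip_mean=104.0, hip_sd=8.0,
        sad_mean=19.7, sad_sd=2.4,
        adiposity_corr=0.8,
        p_diabetes=0.0516, p_prediabetes=0.0525,
        or10_diabetes=4.4, or01_diabetes=1.6, or11_diabetes=4.0,
        or_obese_prediabetes=2.67, or_phd_prediabetes=1.1,
        p_selfreport=0.637, p_med_given_selfreport=0.71, p_nonvalidated=0.13,
        glucose_diabetes=(8.3, 7.1, 12.3),
        glucose_prediabetes=(6.3, 6.1, 6.5),
        glucose_reference=(5.0, 4.7, 5.3),
    )
    return CohortConfig(
        n=4232,
        male_frac=2039 / 4232,
        excluded_frac=3 / 4232,
        men=men,
        women=women,
        missing_rates={
            "smoking": 0.044,
            "leisure_pa": 0.034,
            "work_sedentary": 0.046,
            "height": 0.0005,
            "weight": 0.0005,
            "waist": 0.0007,
            "hip": 0.0007,
            "sad": 0.0012,
        },
    )


# ---------------------------------------------------------------------
# internals

def _cell_weights(sp: SexParams) -> np.ndarray:
    """P(cell) for (A,B) in [(0,0), (1,0), (0,1), (1,1)]; A,B independent."""
    p_a = 1.0 - ndtr((30.0 - sp.bmi_mean) / sp.bmi_sd)  # obesity
    p_b = sp.p_mother + sp.p_father - sp.p_mother * sp.p_father
    return np.array([
        (1 - p_a) * (1 - p_b),
        p_a * (1 - p_b),
        (1 - p_a) * p_b,
        p_a * p_b,
    ])


def _cell_effects(sp: SexParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell log odds (vs reference class) for diabetes, prediabetes."""
    bd = np.log([1.0, sp.or10_diabetes, sp.or01_diabetes, sp.or11_diabetes])
    bp = np.log([
        1.0,
        sp.or_obese_prediabetes,
        sp.or_phd_prediabetes,
        sp.or_obese_prediabetes * sp.or_phd_prediabetes,
    ])
    return bd, bp


def _calibrate_intercepts(sp: SexParams) -> tuple[float, float]:
    """Solve (a_d, a_p) so marginal class prevalences hit their targets."""
    w = _cell_weights(sp)
    bd, bp = _cell_effects(sp)

    def resid(alpha):
        ed = np.exp(alpha[0] + bd)
        ep = np.exp(alpha[1] + bp)
        denom = 1.0 + ed + ep
        return [
            float(w @ (ed / denom)) - sp.p_diabetes,
            float(w @ (ep / denom)) - sp.p_prediabetes,
        ]

    x0 = [float(np.log(sp.p_diabetes / (1 - sp.p_diabetes))),
          float(np.log(sp.p_prediabetes / (1 - sp.p_prediabetes)))]
    sol = root(resid, x0, method="hybr")
    if not sol.success or max(abs(np.array(resid(sol.x)))) > 1e-10:
        raise ConfigError(
            "could not calibrate outcome intercepts to the prevalence "
            f"targets (diabetes={sp.p_diabetes}, prediabetes={sp.p_prediabetes})"
        )
    return float(sol.x[0]), float(sol.x[1])


def _trunc_lognormal(
    rng: np.random.Generator,
    n: int,
    median: float,
    q1: float,
    q3: float,
    lo: float = 0.0,
    hi: float = np.inf,
) -> np.ndarray:
    """Log-normal matched to (median, IQR), truncated to [lo, hi]."""
    mu = np.log(median)
    sigma = (np.log(q3) - np.log(q1)) / (2.0 * _Z75)
    if sigma <= 0:
        return np.full(n, median)
    a = -np.inf if lo <= 0 else (np.log(lo) - mu) / sigma
    b = np.inf if not np.isfinite(hi) else (np.log(hi) - mu) / sigma
    fa, fb = ndtr(a), ndtr(b)
    u = fa + (fb - fa) * rng.random(n)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return np.exp(mu + sigma * ndtri(u))


def _categorical(rng: np.random.Generator, n: int, probs) -> np.ndarray:
    """Draw n categories 0..k-1 from a probability vector."""
    edges = np.cumsum(probs)
    return np.searchsorted(edges, rng.random(n) * edges[-1], side="right")


def generate_cohort(
    config: CohortConfig,
    seed: int,
    return_truth: bool = False,
):
    """Generate a synthetic cohort; identical seed+config => identical cohort.

    With ``return_truth=True`` also returns the latent outcome class per
    record (``diabetes``/``prediabetes``/``reference``/``excluded``),
    against which re-classification can be checked.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n
    male = rng.random(n) < config.male_frac
    sex = np.where(male, "male", "female")

    mother = np.zeros(n, bool)
    father = np.zeros(n, bool)
    sibling = np.zeros(n, bool)
    smoking = np.empty(n, object)
    leisure = np.zeros(n, int)
    work = np.zeros(n, int)
    height = np.zeros(n)
    bmi = np.zeros(n)
    waist = np.zeros(n)
    hip = np.zeros(n)
    sad = np.zeros(n)
    latent = np.empty(n, object)
    glucose = np.full(n, np.nan)
    selfreport = np.full(n, "no", object)
    meds = np.full(n, "no", object)

    for is_male, sp in ((True, config.men), (False, config.women)):
        m = male if is_male else ~male
        k = int(m.sum())
        if k == 0:
            continue
        mo = rng.random(k) < sp.p_mother
        fa = rng.random(k) < sp.p_father
        phd = mo | fa
        sib = rng.random(k) < np.where(
            phd, sp.p_sibling_given_phd, sp.p_sibling_no_phd
        )

        # smoking with optional log-linear dependence on parental history
        logit_cur = np.log(sp.p_current_smoker / (1 - sp.p_current_smoker))
        p_cur = expit(logit_cur + np.where(phd, np.log(sp.smoking_phd_or), 0.0))
        u = rng.random(k)
        smk = np.where(u < p_cur, "current",
                       np.where(u < p_cur + sp.p_ex_smoker, "ex", "never"))

        lei = _categorical(rng, k, sp.leisure_dist) + 1
        wrk = _categorical(rng, k, sp.work_dist) + 1

        z_bmi = rng.standard_normal(k)
        bmi_k = sp.bmi_mean + sp.bmi_sd * z_bmi
        bmi_k = np.maximum(bmi_k, 13.0)  # physiological floor
        obese = bmi_k > 30.0

        rho = sp.adiposity_corr
        mix = np.sqrt(1.0 - rho * rho)
        def _adip(mean, sd):
            return mean + sd * (rho * z_bmi + mix * rng.standard_normal(k))
        waist_k = np.maximum(_adip(sp.waist_mean, sp.waist_sd), 50.0)
        hip_k = np.maximum(_adip(sp.hip_mean, sp.hip_sd), 60.0)
        sad_k = np.maximum(_adip(sp.sad_mean, sp.sad_sd), 10.0)
        height_k = np.maximum(
            sp.height_mean + sp.height_sd * rng.standard_normal(k), 120.0
        )

        # outcome class via baseline-category logit on the (obese, phd) cells
        a_d, a_p = _calibrate_intercepts(sp)
        bd, bp = _cell_effects(sp)
        cell = obese.astype(int) + 2 * phd.astype(int)  # 0:00 1:A 2:B 3:AB
        ed = np.exp(a_d + bd[cell])
        ep = np.exp(a_p + bp[cell])
        denom = 1.0 + ed + ep
        u = rng.random(k)
        cls = np.where(u < ed / denom, "diabetes",
                       np.where(u < (ed + ep) / denom, "prediabetes", "reference"))

        # glucose, self-report and medication consistent with the class
        glu = np.full(k, np.nan)
        sr = np.full(k, "no", object)
        md = np.full(k, "no", object)

        gd = sp.glucose_diabetes
        gp = sp.glucose_prediabetes
        gr = sp.glucose_reference
        is_d = cls == "diabetes"
        nd = int(is_d.sum())
        if nd:
            sr_d = rng.random(nd) < sp.p_selfreport
            nonval = sr_d & (rng.random(nd) < sp.p_nonvalidated)
            med_d = sr_d & ~nonval & (rng.random(nd) < sp.p_med_given_selfreport)
            g = np.empty(nd)
            # glucose-identified or validated-without-medication: >= 7.0
            need_high = ~nonval & ~med_d
            g[need_high] = _trunc_lognormal(
                rng, int(need_high.sum()), *gd, lo=7.0001
            )
            # medicated self-reports: glucose unrestricted (class already set)
            g[med_d] = _trunc_lognormal(rng, int(med_d.sum()), *gd)
            g[nonval] = _trunc_lognormal(rng, int(nonval.sum()), *gd, hi=6.9999)
            di = np.where(is_d)[0]
            glu[di] = g
            sr[di[sr_d]] = "yes"
            md[di[med_d]] = "yes"
        is_p = cls == "prediabetes"
        glu[is_p] = _trunc_lognormal(
            rng, int(is_p.sum()), *gp, lo=6.1, hi=6.8999
        )
        is_r = cls == "reference"
        glu[is_r] = _trunc_lognormal(rng, int(is_r.sum()), *gr, hi=6.0999)

        idx = np.where(m)[0]
        mother[idx] = mo
        father[idx] = fa
        sibling[idx] = sib
        smoking[idx] = smk
        leisure[idx] = lei
        work[idx] = wrk
        height[idx] = height_k
        bmi[idx] = bmi_k
        waist[idx] = waist_k
        hip[idx] = hip_k
        sad[idx] = sad_k
        latent[idx] = cls
        glucose[idx] = glu
        selfreport[idx] = sr
        meds[idx] = md

    # excluded records: no glucose, diabetes question left blank
    excl = rng.random(n) < config.excluded_frac
    latent[excl] = "excluded"
    glucose[excl] = np.nan
    selfreport[excl] = "blank"
    meds[excl] = "no"

    weight = bmi * (height / 100.0) ** 2

    df = pd.DataFrame(
        {
            "id": [f"s{i:06d}" for i in range(n)],
            "sex": sex,
            "selfreport_diabetes": selfreport,
            "fasting_glucose": glucose,
            "antidiabetic_medication": meds,
            "mother_diabetes": np.where(mother, "yes", "no"),
            "father_diabetes": np.where(father, "yes", "no"),
            "sibling_diabetes": np.where(sibling, "yes", "no"),
            "smoking": smoking,
            "leisure_pa": pd.array(leisure, dtype="Int64"),
            "work_sedentary": pd.array(work, dtype="Int64"),
            "height": height,
            "weight": weight,
            "waist": waist,
            "hip": hip,
            "sad": sad,
        }
    )

    # missingness mask (never applied to the outcome-defining fields)
    for col, rate in config.missing_rates.items():
        if rate <= 0:
            continue
        mask = rng.random(n) < rate
        if col == "smoking":
            df.loc[mask, col] = np.nan
        elif col in ("leisure_pa", "work_sedentary"):
            arr = df[col].copy()
            arr[mask] = pd.NA
            df[col] = arr
        else:
            df.loc[mask, col] = np.nan
    # weight follows height missingness only through its own mask; keep
    # bmi missing whenever either ingredient is missing
    df.loc[df["height"].isna(), "weight"] = np.nan

    cohort = Cohort(df=df, provenance=f"synthetic(seed={seed}, n={n})")
    if return_truth:
        return cohort, pd.Series(latent, index=df.index, name="latent_outcome")
    return cohort
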