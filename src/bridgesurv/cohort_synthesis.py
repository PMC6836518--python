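"""Synthetic patient data, virtual cohorts and the interdependence screen.

The cross-sectional dataset the hazard model's covariate distributions come
from is not public, so this module ships a synthetic stand-in generator.
Its default parameters (prevalences, regression coefficients, residual
spreads) are synthetic placeholders chosen to be clinically plausible for an
elderly, progressively weakening myositis population; they are calibrated
only to two anchors — patients older than 45 and a median 6-minute-walk
deficit of roughly 281 m versus the age/sex-matched general population —
and must not be read as estimates from any real cohort.

Generation rules
----------------
* age ~ Normal(mean, sd) truncated at ``min_age``; sex ~ Bernoulli(prop_male)
* height ~ sex-specific Normal (cm)
* weight = linear regression on age, sex, height + Normal residual (kg)
* falls ~ Bernoulli(prev_falls)
* swallowing score: point mass at 0 with probability 1 - prev_dysphagia,
  otherwise uniform on [1, 10]; dysphagia = 1{score >= 1}
* lower-body severity ~ Multinomial(mild, moderate, severe); severe patients
  are wheelchair-bound
* 6MWD = linear regression on age, height, weight + residual, floored at 0,
  and forced to 0 for wheelchair users
* aspiration pneumonia ~ Bernoulli(baseline prevalence, multiplied by a
  published risk ratio when the patient has dysphagia)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .baseline_lifetable import LifeTable

__all__ = [
    "CohortSpec",
    "VirtualPatient",
    "generate_tma_like_dataset",
    "generate_virtual_cohort",
    "dichotomize_swallowing",
    "impute_aspiration_pneumonia",
    "spearman_matrix",
    "sample_general_pop_6mwd",
    "generate_life_table",
    "attach_reference_6mwd",
    "check_cohort_invariants",
    "DEFAULT_REFERENCE_6MWD",
]

SEVERITY_LEVELS = ("mild", "moderate", "severe")

# General-population 6MWD reference (metres) by age band and sex: synthetic
# values in the range healthy-adult walking norms occupy, declining with age.
DEFAULT_REFERENCE_6MWD: dict[str, list[tuple[float, float, float, float]]] = {
    # (age_lo, age_hi, mean_m, sd_m)
    "male": [(45, 55, 620.0, 85.0), (55, 65, 580.0, 85.0), (65, 75, 540.0, 85.0),
             (75, 85, 470.0, 85.0), (85, 121, 400.0, 85.0)],
    "female": [(45, 55, 580.0, 85.0), (55, 65, 540.0, 85.0), (65, 75, 500.0, 85.0),
               (75, 85, 430.0, 85.0), (85, 121, 360.0, 85.0)],
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic patient generator (all placeholders).

    Regression coefficient tuples are ordered (intercept, age, male, height)
    for weight and (intercept, age, height, weight) for 6MWD; residual sd is
    the last element of each tuple.
    """

    n: int = 102
    age_mean: float = 67.0
    age_sd: float = 9.0
    min_age: float = 45.0
    prop_male: float = 0.55
    height_mean_male: float = 175.0
    height_sd_male: float = 7.0
    height_mean_female: float = 162.0
    height_sd_female: float = 6.0
    # weight [kg] = b0 + b_age*age + b_male*male + b_height*height + N(0, sd)
    weight_regression: tuple[float, float, float, float, float] = (-15.0, -0.10, 5.0, 0.55, 9.0)
    # 6MWD [m] = b0 + b_age*age + b_height*height + b_weight*weight + N(0, sd)
    six_mwd_regression: tuple[float, float, float, float, float] = (473.0, -5.5, 1.5, -1.0, 80.0)
    prev_falls: float = 0.35
    prev_dysphagia: float = 0.50
    severity_probs: tuple[float, float, float] = (0.45, 0.35, 0.20)
    ap_baseline_prev: float = 0.01
    ap_rr_given_dysphagia: float = 9.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prop_male", "prev_falls", "prev_dysphagia", "ap_baseline_prev"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.severity_probs) - 1.0) > 1e-9:
            raise ValueError("severity_probs must sum to 1")
        if any(p < 0 for p in self.severity_probs):
            raise ValueError("severity_probs must be non-negative")
        for name in ("age_sd", "height_sd_male", "height_sd_female"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.weight_regression[-1] <= 0 or self.six_mwd_regression[-1] <= 0:
            raise ValueError("regression residual sds must be positive")
        if self.ap_baseline_prev * self.ap_rr_given_dysphagia > 1.0:
            raise ValueError("aspiration-pneumonia probability exceeds 1 for dysphagia patients")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    def with_(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class VirtualPatient:
    """One simulated patient; invariants enforced on construction."""

    age: float
    sex: str
    height: float
    weight: float
    falls: int
    dysphagia: int
    aspiration_pneumonia: int
    severity: str
    wheelchair: int
    six_mwd: float

    def __post_init__(self) -> None:
        if self.wheelchair and self.six_mwd != 0.0:
            raise ValueError("wheelchair users must have six_mwd = 0")
        if self.severity == "severe" and not self.wheelchair:
            raise ValueError("severe lower-body impairment implies wheelchair use")
        if self.six_mwd < 0:
            raise ValueError("six_mwd must be >= 0")


def dichotomize_swallowing(score: float) -> int:
    """Presence of dysphagia: 1 iff the 0-10 swallowing score is >= 1."""
    if score < 0:
        raise ValueError("swallowing score must be non-negative")
    return int(score >= 1.0)


def impute_aspiration_pneumonia(dysphagia: int, spec: CohortSpec,
                                rng: np.random.Generator) -> int:
    """Bernoulli imputation: baseline prevalence, scaled by the published
    risk ratio when the patient has dysphagia."""
    p = spec.ap_baseline_prev * (spec.ap_rr_given_dysphagia if dysphagia else 1.0)
    if p > 1.0:
        raise ValueError("imputation probability exceeds 1")
    return int(rng.uniform() < p)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float, size: int) -> np.ndarray:
    a = (lower - mean) / sd
    u = rng.uniform(stats.norm.cdf(a), 1.0, size=size)
    return mean + sd * stats.norm.ppf(u)


def _generate(spec: CohortSpec, n: int, rng: np.random.Generator,
              ages: np.ndarray | None = None,
              male: np.ndarray | None = None) -> pd.DataFrame:
    if ages is None:
        ages = _truncated_normal(rng, spec.age_mean, spec.age_sd, spec.min_age, n)
    if male is None:
        male = (rng.uniform(size=n) < spec.prop_male).astype(int)
    sex = np.where(male == 1, "male", "female")
    height = np.where(
        male == 1,
        rng.normal(spec.height_mean_male, spec.height_sd_male, size=n),
        rng.normal(spec.height_mean_female, spec.height_sd_female, size=n),
    )
    b0, b_age, b_male, b_height, w_sd = spec.weight_regression
    weight = (b0 + b_age * ages + b_male * male + b_height * height
              + rng.normal(0.0, w_sd, size=n))
    weight = np.maximum(weight, 30.0)  # physiological floor

    falls = (rng.uniform(size=n) < spec.prev_falls).astype(int)

    has_dys = rng.uniform(size=n) < spec.prev_dysphagia
    swallow_score = np.where(has_dys, rng.uniform(1.0, 10.0, size=n), 0.0)
    dysphagia = np.array([dichotomize_swallowing(s) for s in swallow_score])

    severity_idx = rng.choice(3, size=n, p=np.asarray(spec.severity_probs))
    severity = np.array(SEVERITY_LEVELS)[severity_idx]
    wheelchair = (severity == "severe").astype(int)

    c0, c_age, c_height, c_weight, m_sd = spec.six_mwd_regression
    six_mwd = (c0 + c_age * ages + c_height * height + c_weight * weight
               + rng.normal(0.0, m_sd, size=n))
    six_mwd = np.maximum(six_mwd, 0.0)
    six_mwd = np.where(wheelchair == 1, 0.0, six_mwd)

    p_ap = spec.ap_baseline_prev * np.where(dysphagia == 1, spec.ap_rr_given_dysphagia, 1.0)
    if np.any(p_ap > 1.0):
        raise ValueError("aspiration-pneumonia probability exceeds 1")
    aspiration = (rng.uniform(size=n) < p_ap).astype(int)

    return pd.DataFrame({
        "age": ages, "sex": sex, "height": height, "weight": weight,
        "falls": falls, "swallow_score": swallow_score, "dysphagia": dysphagia,
        "severity": severity, "wheelchair": wheelchair, "six_mwd": six_mwd,
        "aspiration_pneumonia": aspiration,
    })


def generate_tma_like_dataset(spec: CohortSpec,
                              rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Synthetic cross-sectional patient table with ``spec.n`` rows.

    Reproducible from ``spec.seed`` when no generator is passed.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return _generate(spec, spec.n, rng)


def generate_virtual_cohort(spec: CohortSpec, study_age_sex: dict,
                            n: int | None = None,
                            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Virtual cohort with ages/sexes matched to a validation study.

    ``study_age_sex`` carries ``age_mean``, ``age_sd``, ``prop_male`` (and
    optionally ``min_age``); all other covariates follow the CohortSpec rules,
    with severity -> wheelchair and wheelchair -> 6MWD=0 enforced in that order.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n if n is None else n
    min_age = float(study_age_sex.get("min_age", spec.min_age))
    ages = _truncated_normal(rng, float(study_age_sex["age_mean"]),
                             float(study_age_sex["age_sd"]), min_age, n)
    male = (rng.uniform(size=n) < float(study_age_sex["prop_male"])).astype(int)
    return _generate(spec, n, rng, ages=ages, male=male)


def check_cohort_invariants(df: pd.DataFrame) -> None:
    """Raise if any row violates the VirtualPatient invariants."""
    if (df.loc[df["wheelchair"] == 1, "six_mwd"] != 0).any():
        raise AssertionError("wheelchair user with non-zero six_mwd")
    if (df.loc[df["severity"] == "severe", "wheelchair"] != 1).any():
        raise AssertionError("severe severity without wheelchair")
    if (df["six_mwd"] < 0).any():
        raise AssertionError("negative six_mwd")
    if ((df["swallow_score"] >= 1).astype(int) != df["dysphagia"]).any():
        raise AssertionError("dysphagia flag inconsistent with swallowing score")


def sample_general_pop_6mwd(age, sex, params=None,
                            rng: np.random.Generator | None = None) -> float | np.ndarray:
    """Draw reference 6-minute walking distances for healthy individuals.

    ``params`` maps sex -> list of (age_lo, age_hi, mean, sd) bands; draws are
    normal within the matching band, floored at 0 metres.
    """
    if params is None:
        params = DEFAULT_REFERENCE_6MWD
    if rng is None:
        rng = np.random.default_rng()
    scalar = np.isscalar(age)
    ages = np.atleast_1d(np.asarray(age, dtype=float))
    sexes = np.atleast_1d(np.asarray(sex))
    if sexes.size == 1 and ages.size > 1:
        sexes = np.repeat(sexes, ages.size)
    out = np.empty(ages.size)
    for i, (a, s) in enumerate(zip(ages, sexes)):
        bands = params.get(str(s))
        if bands is None:
            raise KeyError(f"no reference 6MWD bands for sex {s!r}")
        for lo, hi, mean, sd in bands:
            if lo <= a < hi:
                out[i] = max(0.0, mean + sd * rng.standard_normal()) if sd > 0 else mean
                break
        else:
            raise KeyError(f"no reference 6MWD band covers age {a}")
    return float(out[0]) if scalar else out


def attach_reference_6mwd(df: pd.DataFrame, params=None,
                          rng: np.random.Generator | None = None,
                          floor_deficit: bool = False) -> pd.DataFrame:
    """Add ``ref_6mwd`` (matched general-population draw) and ``d6mwd``
    (metre deficit = ref - patient, positive when impaired)."""
    out = df.copy()
    out["ref_6mwd"] = sample_general_pop_6mwd(
        df["age"].to_numpy(), df["sex"].to_numpy(), params=params, rng=rng)
    d = out["ref_6mwd"] - out["six_mwd"]
    out["d6mwd"] = np.maximum(d, 0.0) if floor_deficit else d
    return out


def spearman_matrix(table: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Spearman rank correlations (average-rank ties) between the variables.

    Constant columns give NaN entries and a warning rather than a silent 0.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    sub = table[variables].astype(float)
    constant = [v for v in variables if sub[v].nunique() <= 1]
    if constant:
        warnings.warn(f"constant columns (undefined correlation): {constant}",
                      stacklevel=2)
    mat = sub.corr(method="spearman")
    np.fill_diagonal(mat.values, 1.0)
    for v in constant:
        mat.loc[v, :] = np.nan
        mat.loc[:, v] = np.nan
        mat.loc[v, v] = np.nan
    return mat


def generate_life_table(shape: float, scale: float, bands=None, sex: str = "male",
                        noise_sd: float = 0.0,
                        rng: np.random.Generator | None = None) -> LifeTable:
    """Life-table fixture whose band death rates come from exact Weibull
    band probabilities, optionally perturbed by multiplicative lognormal noise.

    The rate for band [a, b) is the average hazard
    ``m = -log(S(b)/S(a)) / (b - a)``, so ``1 - exp(-m*(b-a))`` recovers the
    exact conditional band death probability.
    """
    if shape <= 0 or scale <= 0:
        raise ValueError("shape and scale must be positive")
    if bands is None:
        bands = [(a, a + 5) for a in range(45, 100, 5)]
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for a, b in bands:
        log_sa = -((a / scale) ** shape)
        log_sb = -((b / scale) ** shape)
        m = (log_sa - log_sb) / (b - a)
        if noise_sd > 0:
            m *= math.exp(rng.normal(0.0, noise_sd))
        rows.append({"sex": sex, "age_lo": float(a), "age_hi": float(b),
                     "death_rate": m, "deaths": np.nan, "population": np.nan})
    return LifeTable(pd.DataFrame(rows))
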