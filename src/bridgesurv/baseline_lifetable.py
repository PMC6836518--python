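"""Sex-specific Weibull reference survival fitted to grouped life tables.

A life table gives all-cause death rates in 5-year age bands by sex.  Each
band [a, b) is converted to a conditional death probability
``q = 1 - exp(-rate * width)`` and the two-parameter Weibull survival
``S(t) = exp(-(t/scale)^shape)`` is fitted by maximising the grouped
interval-censored binomial likelihood

    sum_k  d_k log q_k(theta) + (N_k - d_k) log(1 - q_k(theta)),
    q_k(theta) = 1 - S(b_k)/S(a_k),

i.e. each band's pseudo-cohort is left-truncated at its own lower bound.
Bands below ``fit_min_age`` (default 45, the usual lower age bound of the
target disease population) are excluded; because every band conditions on
survival to its own start, the fit is invariant to those dropped bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "LifeTable",
    "WeibullBaseline",
    "WeibullLifetableModel",
    "WeibullBaselineResults",
    "read_life_table",
    "fit_weibull",
    "survival_at",
    "conditional_survival",
]

SEXES = ("male", "female")
DEFAULT_PSEUDO_POP = 100_000  # per-band cohort size when only rates are given


class LifeTableFormatError(ValueError):
    """Malformed life-table input (overlapping bands, negative rates, ...)."""


class FitError(RuntimeError):
    """The Weibull optimiser failed to converge."""


@dataclass
class LifeTable:
    """Grouped death rates by sex and age band, backed by a DataFrame.

    Columns: sex, age_lo, age_hi, death_rate (per person-year), and optional
    deaths / population counts.  Bands are half-open [age_lo, age_hi); an
    open-ended final band is encoded with age_hi = inf.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"sex", "age_lo", "age_hi", "death_rate"}
        missing = required - set(df.columns)
        if missing:
            raise LifeTableFormatError(f"missing columns: {sorted(missing)}")
        if (df["death_rate"] < 0).any():
            raise LifeTableFormatError("negative death rate")
        if (df["age_lo"] >= df["age_hi"]).any():
            raise LifeTableFormatError("age_lo must be < age_hi")
        bad_sex = set(df["sex"]) - set(SEXES)
        if bad_sex:
            raise LifeTableFormatError(f"unknown sex values: {sorted(bad_sex)}")
        for sex, grp in df.groupby("sex"):
            g = grp.sort_values("age_lo")
            if (g["age_lo"].values[1:] < g["age_hi"].values[:-1]).any():
                raise LifeTableFormatError(f"overlapping age bands for sex={sex}")
        self.data = df.sort_values(["sex", "age_lo"]).reset_index(drop=True)

    def for_sex(self, sex: str) -> pd.DataFrame:
        if sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        return self.data[self.data["sex"] == sex].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def read_life_table(path) -> LifeTable:
    """Read and validate a life-table CSV
    (sex,age_lo,age_hi,death_rate[,deaths,population])."""
    df = pd.read_csv(path)
    df["age_hi"] = df["age_hi"].replace({np.inf: np.inf})
    return LifeTable(df)


@dataclass(frozen=True)
class WeibullBaseline:
    """Fitted Weibull reference survival for one sex.

    ``S(t) = exp(-(t/scale)^shape)``; ``fit_min_age`` records the lower age
    restriction of the fit (survival below it extrapolates the same curve).
    """

    sex: str
    shape: float
    scale: float
    fit_min_age: float = 45.0
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be positive")

    def survival(self, t) -> np.ndarray | float:
        return survival_at(self, t)

    def hazard(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        return self.shape / self.scale * (t / self.scale) ** (self.shape - 1.0)

    def conditional_survival(self, t, age0) -> np.ndarray | float:
        return conditional_survival(self, t, age0)

    def to_dict(self) -> dict:
        return {"sex": self.sex, "shape": self.shape, "scale": self.scale,
                "fit_min_age": self.fit_min_age, "loglik": self.loglik}

    @classmethod
    def from_dict(cls, d: dict) -> "WeibullBaseline":
        return cls(sex=d["sex"], shape=float(d["shape"]), scale=float(d["scale"]),
                   fit_min_age=float(d.get("fit_min_age", 45.0)),
                   loglik=float(d.get("loglik", float("nan"))))


def survival_at(baseline: WeibullBaseline, t) -> np.ndarray | float:
    """Weibull survival S(t) = exp(-(t/scale)^shape); t >= 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    out = np.exp(-((t_arr / baseline.scale) ** baseline.shape))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def conditional_survival(baseline: WeibullBaseline, t, age0) -> np.ndarray | float:
    """Survival to t conditional on being alive at age0: S(t)/S(age0)."""
    t_arr = np.asarray(t, dtype=float)
    a_arr = np.asarray(age0, dtype=float)
    if np.any(t_arr < a_arr):
        raise ValueError("t must be >= age0")
    out = np.exp((a_arr / baseline.scale) ** baseline.shape
                 - (t_arr / baseline.scale) ** baseline.shape)
    scalar = np.isscalar(t) and np.isscalar(age0)
    return float(out) if scalar or out.ndim == 0 else out


def _band_arrays(df: pd.DataFrame, fit_min_age: float, pseudo_pop: int):
    """Deaths / populations per closed band at or above fit_min_age."""
    df = df[df["age_lo"] >= fit_min_age]
    df = df[np.isfinite(df["age_hi"])]  # open-ended band carries no interval info here
    if len(df) < 3:
        raise FitError("need >=3 closed bands at or above fit_min_age")
    a = df["age_lo"].to_numpy(float)
    b = df["age_hi"].to_numpy(float)
    width = b - a
    have_counts = ("deaths" in df.columns and "population" in df.columns
                   and df["deaths"].notna().all() and df["population"].notna().all())
    if have_counts:
        n_k = df["population"].to_numpy(float)
        d_k = df["deaths"].to_numpy(float)
    else:
        q = 1.0 - np.exp(-df["death_rate"].to_numpy(float) * width)
        n_k = np.full(len(df), float(pseudo_pop))
        d_k = n_k * q
    return a, b, d_k, n_k


def fit_weibull(table: LifeTable, sex: str, fit_min_age: float = 45.0,
                pseudo_pop: int = DEFAULT_PSEUDO_POP) -> WeibullBaseline:
    """Fit the Weibull baseline for one sex by grouped interval-censored ML.

    When death/population counts are absent, each band's per-person-year rate
    m is converted to a band death probability ``q = 1 - exp(-m * width)`` and
    a fixed pseudo-population per band weights the bands equally.
    Optimised on (log shape, log scale) with three starts.
    """
    df = table.for_sex(sex)
    if (df["death_rate"] == 0).all():
        raise FitError("all-zero death rates: survival is unidentifiable")
    a, b, d_k, n_k = _band_arrays(df, fit_min_age, pseudo_pop)
    s_k = n_k - d_k

    def negloglik(params: np.ndarray) -> float:
        shape = math.exp(params[0])
        scale = math.exp(params[1])
        ha = (a / scale) ** shape
        hb = (b / scale) ** shape
        # q_k = 1 - exp(-(hb - ha)), conditional on survival to the band start
        dh = np.clip(hb - ha, 1e-300, None)
        log_surv = -dh
        log_q = np.log1p(-np.exp(-dh))
        return -float(np.sum(d_k * log_q + s_k * log_surv))

    starts = [(math.log(s0), math.log(c0))
              for s0, c0 in ((1.0, 80.0), (5.0, 85.0), (8.0, 90.0))]
    best = None
    for x0 in starts:
        res = minimize(negloglik, x0=np.array(x0), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("Weibull fit did not converge")
    shape = math.exp(best.x[0])
    scale = math.exp(best.x[1])
    return WeibullBaseline(sex=sex, shape=shape, scale=scale,
                           fit_min_age=fit_min_age, loglik=-best.fun)


class WeibullLifetableModel:
    """Model object wrapping a life table; ``fit()`` returns per-sex baselines.

    >>> model = WeibullLifetableModel(table, fit_min_age=45)
    >>> results = model.fit()
    >>> results["male"].shape, results["male"].scale  # doctest: +SKIP
    """

    def __init__(self, table: LifeTable, fit_min_age: float = 45.0,
                 pseudo_pop: int = DEFAULT_PSEUDO_POP) -> None:
        self.table = table
        self.fit_min_age = fit_min_age
        self.pseudo_pop = pseudo_pop

    def fit(self, sexes=SEXES) -> "WeibullBaselineResults":
        fits = {}
        for sex in sexes:
            if (self.table.data["sex"] == sex).any():
                fits[sex] = fit_weibull(self.table, sex, self.fit_min_age,
                                        self.pseudo_pop)
        if not fits:
            raise FitError("no rows for any requested sex")
        return WeibullBaselineResults(self, fits)


class WeibullBaselineResults:
    """Per-sex fitted Weibull baselines with a summary table."""

    def __init__(self, model: WeibullLifetableModel,
                 fits: dict[str, WeibullBaseline]) -> None:
        self.model = model
        self.fits = fits

    def __getitem__(self, sex: str) -> WeibullBaseline:
        return self.fits[sex]

    def __contains__(self, sex: str) -> bool:
        return sex in self.fits

    def summary(self) -> pd.DataFrame:
        rows = [f.to_dict() for f in self.fits.values()]
        return pd.DataFrame(rows).set_index("sex")

    def to_dict(self) -> dict:
        return {sex: f.to_dict() for sex, f in self.fits.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "WeibullBaselineResults":
        fits = {sex: WeibullBaseline.from_dict(v) for sex, v in d.items()}
        return cls(model=None, fits=fits)
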