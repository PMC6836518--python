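"""Multiplicative hazard model over functional predictors.

Each patient's log relative hazard versus the age/sex-matched general
population is a sum of coefficient * covariate terms over the active
predictor subset

    eta_i = beta_dys*dys_i + beta_ap*AP_i + beta_falls*falls_i
            + beta_6mwd*d6mwd_i + beta_wch*wch_i,     HR_i = exp(eta_i),

where ``d6mwd_i`` is the patient's walking-distance deficit in metres
relative to the general-population reference (positive = impaired) and the
binary predictors are presence indicators.  The individual intercept is the
age/sex-specific baseline hazard, delivered by the sex-matched Weibull
reference curve with left truncation at the patient's baseline age — no
free intercept is estimated.  Adjusted survival is the proportional-hazards
power law ``[S(t)/S(age0)]^HR`` and death times are drawn by inverting the
left-truncated adjusted Weibull CDF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .baseline_lifetable import WeibullBaseline, conditional_survival

__all__ = [
    "Coefficient",
    "CoefficientSet",
    "LinearPredictor",
    "linear_predictor",
    "hr_from_delta",
    "adjusted_survival",
    "simulate_death_time",
    "ALL_COVARIATES",
]

ALL_COVARIATES = ("six_mwd", "dysphagia", "falls", "wheelchair", "aspiration_pneumonia")

# patient attribute supplying each covariate's model value
_COVARIATE_FIELDS = {
    "dysphagia": "dysphagia",
    "falls": "falls",
    "wheelchair": "wheelchair",
    "aspiration_pneumonia": "aspiration_pneumonia",
    "six_mwd": "d6mwd",  # metre deficit vs the reference, not the raw distance
}


@dataclass(frozen=True)
class Coefficient:
    """One predictor's log-hazard coefficient, optionally with posterior samples.

    ``per_unit`` documents the covariate unit (1 for presence indicators,
    'per metre lost' for walking distance).  Positive values always mean
    higher hazard per unit of the covariate.
    """

    point: float
    samples: np.ndarray | None = None
    per_unit: str = "presence"

    def draw(self, rng: np.random.Generator) -> float:
        if self.samples is None:
            return self.point
        return float(self.samples[rng.integers(self.samples.size)])


@dataclass
class CoefficientSet:
    """Map predictor name -> :class:`Coefficient`."""

    coeffs: dict[str, Coefficient] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {c.samples.size for c in self.coeffs.values() if c.samples is not None}
        if len(lengths) > 1:
            raise ValueError("coefficient sample sequences must have equal length")

    def __getitem__(self, name: str) -> Coefficient:
        return self.coeffs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.coeffs

    def points(self, active=None) -> dict[str, float]:
        names = self.coeffs if active is None else active
        return {k: self.coeffs[k].point for k in names}

    def draw_vector(self, rng: np.random.Generator, active=None) -> dict[str, float]:
        """One joint draw (independent components) of the active coefficients."""
        names = self.coeffs if active is None else active
        return {k: self.coeffs[k].draw(rng) for k in names}

    @classmethod
    def from_points(cls, **points: float) -> "CoefficientSet":
        return cls({k: Coefficient(point=v) for k, v in points.items()})


@dataclass(frozen=True)
class LinearPredictor:
    """Log relative hazard eta and its hazard ratio exp(eta)."""

    eta: float

    @property
    def hr(self) -> float:
        return math.exp(self.eta)


def _covariate_value(patient, name: str) -> float:
    attr = _COVARIATE_FIELDS[name]
    if isinstance(patient, dict):
        if attr not in patient or patient[attr] is None:
            raise KeyError(f"patient is missing covariate {attr!r} needed for {name!r}")
        return float(patient[attr])
    value = getattr(patient, attr, None)
    if value is None:
        raise KeyError(f"patient is missing covariate {attr!r} needed for {name!r}")
    return float(value)


def linear_predictor(patient, coeffs, active=None) -> LinearPredictor:
    """Sum coefficient * covariate over the active subset; inactive terms are 0.

    ``coeffs`` is a CoefficientSet (point values used) or a plain mapping
    predictor -> float; ``active`` defaults to every predictor that has a
    coefficient.  ``patient`` is a VirtualPatient or dict; the six_mwd
    covariate reads the metre deficit field ``d6mwd``.
    """
    if active is None:
        active = tuple(coeffs.coeffs if isinstance(coeffs, CoefficientSet) else coeffs)
    eta = 0.0
    for name in active:
        if isinstance(coeffs, CoefficientSet):
            if name not in coeffs:
                raise KeyError(f"no coefficient for active covariate {name!r}")
            beta = coeffs[name].point
        else:
            beta = float(coeffs[name])
        eta += beta * _covariate_value(patient, name)
    return LinearPredictor(eta=eta)


def hr_from_delta(beta: float, delta_x: float) -> float:
    """Hazard ratio for a covariate shift: HR = exp(beta * delta_x)."""
    if not (math.isfinite(beta) and math.isfinite(delta_x)):
        raise ValueError("beta and delta_x must be finite")
    return math.exp(beta * delta_x)


def adjusted_survival(baseline: WeibullBaseline, lp, t, age0) -> float | np.ndarray:
    """[S(t)/S(age0)]^HR — hazard-adjusted, left-truncated survival."""
    hr = lp.hr if isinstance(lp, LinearPredictor) else float(lp)
    base = conditional_survival(baseline, t, age0)
    return base ** hr


def simulate_death_time(baseline: WeibullBaseline, lp, age0, rng,
                        size=None) -> float | np.ndarray:
    """Inverse-CDF draw(s) of the age at death given survival to age0.

    ``t = scale * [(age0/scale)^shape - ln(U)/HR]^(1/shape)``, U ~ U(0,1);
    the result is almost surely > age0.  ``age0`` may be an array (one draw
    per entry when ``size`` is None).
    """
    hr = lp.hr if isinstance(lp, LinearPredictor) else float(lp)
    age0_arr = np.asarray(age0, dtype=float)
    if np.any(age0_arr < 0):
        raise ValueError("age0 must be non-negative")
    shape, scale = baseline.shape, baseline.scale
    n = age0_arr.shape if size is None else size
    u = rng.uniform(size=n if n != () else None)
    t = scale * ((age0_arr / scale) ** shape - np.log(u) / hr) ** (1.0 / shape)
    if np.isscalar(age0) and size is None:
        return float(t)
    return t
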