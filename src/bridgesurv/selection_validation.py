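"""Covariate-subset enumeration, predicted-mortality simulation and
coverage-based model selection.

Candidate models are subsets of {6MWD, dysphagia, falls, wheelchair,
aspiration pneumonia}.  Each candidate is scored by simulating replicate
virtual cohorts matched to a validation study's size and age/sex mix,
computing the percent dying within the study's median follow-up under the
proportional-hazards model, and checking whether the equal-tailed 95%
interval over replicates covers the study's observed death percentage.  The
selected model is the most parsimonious among those with the best coverage
and smallest median absolute difference from the observed value.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .baseline_lifetable import WeibullBaselineResults, conditional_survival
from .cohort_synthesis import CohortSpec, attach_reference_6mwd, generate_virtual_cohort
from .hazard_model import ALL_COVARIATES, CoefficientSet, linear_predictor

__all__ = [
    "ValidationStudy",
    "ModelCandidate",
    "enumerate_models",
    "simulate_study_mortality",
    "coverage_statistic",
    "rank_and_select",
    "read_validation_studies",
]


@dataclass(frozen=True)
class ValidationStudy:
    """Published mortality summary used as the external validation target."""

    label: str
    n: int
    followup_years: float
    observed_death_pct: float
    observed_ci: tuple[float, float]
    age_mean: float
    age_sd: float
    prop_male: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.observed_death_pct <= 100.0:
            raise ValueError("observed_death_pct must be in [0, 100]")
        if self.observed_ci[0] > self.observed_ci[1]:
            raise ValueError("observed CI must be ordered")

    @property
    def age_sex(self) -> dict:
        return {"age_mean": self.age_mean, "age_sd": self.age_sd,
                "prop_male": self.prop_male}


def read_validation_studies(path) -> list[ValidationStudy]:
    """Read `label,n,followup_years,observed_death_pct,ci_low,ci_high,
    age_mean,age_sd,prop_male`."""
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        out.append(ValidationStudy(
            label=str(row.label), n=int(row.n),
            followup_years=float(row.followup_years),
            observed_death_pct=float(row.observed_death_pct),
            observed_ci=(float(row.ci_low), float(row.ci_high)),
            age_mean=float(row.age_mean), age_sd=float(row.age_sd),
            prop_male=float(row.prop_male),
        ))
    return out


@dataclass
class ModelCandidate:
    """A covariate subset with its simulated predicted-mortality summary."""

    covariates: tuple[str, ...]
    predicted_death_pct: float = float("nan")
    predicted_cri: tuple[float, float] = (float("nan"), float("nan"))
    covered: bool = False
    median_abs_diff: float = float("nan")
    n_replicates: int = 0

    @property
    def size(self) -> int:
        return len(self.covariates)

    def to_dict(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "predicted_death_pct": self.predicted_death_pct,
            "predicted_cri": list(self.predicted_cri),
            "covered": self.covered,
            "median_abs_diff": self.median_abs_diff,
            "n_replicates": self.n_replicates,
        }


def enumerate_models(covariates=ALL_COVARIATES, stepwise_from: tuple[str, ...] | None = None
                     ) -> list[tuple[str, ...]]:
    """All covariate subsets (including the empty null model), ordered by
    size then lexicographically.

    With ``stepwise_from``, subsets of size > len(stepwise_from) are
    restricted to supersets of that seed model (stepwise-forward expansion).
    """
    covariates = tuple(covariates)
    if len(covariates) > 10:
        raise ValueError("too many covariates to enumerate")
    subsets: list[tuple[str, ...]] = []
    for k in range(len(covariates) + 1):
        level = sorted(tuple(sorted(c)) for c in combinations(covariates, k))
        if stepwise_from is not None and k > len(stepwise_from):
            seed = set(stepwise_from)
            level = [s for s in level if seed.issubset(s)]
        subsets.extend(level)
    return subsets


def _simulate_replicate_death_pct(cohort: pd.DataFrame, covariates, baselines,
                                  coeffs: CoefficientSet, followup: float,
                                  rng: np.random.Generator) -> float:
    """Percent of one virtual cohort dying within the follow-up horizon."""
    n = len(cohort)
    u = rng.uniform(size=n)
    died = 0
    records = cohort.to_dict("records")
    for i, patient in enumerate(records):
        beta = coeffs.draw_vector(rng, active=covariates)
        lp = linear_predictor(patient, beta, active=covariates)
        base = baselines[patient["sex"]]
        age0 = float(patient["age"])
        surv = conditional_survival(base, age0 + followup, age0) ** lp.hr
        died += u[i] >= surv
    return 100.0 * died / n


def simulate_study_mortality(covariates, spec: CohortSpec, study: ValidationStudy,
                             baselines: WeibullBaselineResults | dict,
                             coeffs: CoefficientSet, n_replicates: int = 500,
                             seed: int = 0,
                             reference_6mwd_params=None) -> ModelCandidate:
    """Simulate the candidate model's predicted death percentage distribution.

    Each replicate generates a fresh cohort of ``study.n`` patients matched to
    the study's age/sex mix, draws one coefficient vector per patient (when
    posterior samples are attached), and records the percent dying within the
    study's median follow-up.  The predicted CrI is the equal-tailed 95%
    interval over replicates.
    """
    covariates = tuple(sorted(covariates))
    for c in covariates:
        if c not in coeffs:
            raise KeyError(f"no coefficient supplied for covariate {c!r}")
    rng = np.random.default_rng(int(seed))
    pcts = np.empty(n_replicates)
    for r in range(n_replicates):
        cohort = generate_virtual_cohort(spec, study.age_sex, n=study.n, rng=rng)
        if "six_mwd" in covariates:
            cohort = attach_reference_6mwd(cohort, params=reference_6mwd_params, rng=rng)
        else:
            cohort = cohort.assign(d6mwd=0.0)
        pcts[r] = _simulate_replicate_death_pct(
            cohort, covariates, baselines, coeffs, study.followup_years, rng)
    med = float(np.median(pcts))
    cri = (float(np.quantile(pcts, 0.025)), float(np.quantile(pcts, 0.975)))
    covered, diff = coverage_statistic(cri, study.observed_death_pct, median_pred=med)
    return ModelCandidate(
        covariates=covariates, predicted_death_pct=med, predicted_cri=cri,
        covered=covered, median_abs_diff=diff, n_replicates=n_replicates,
    )


def coverage_statistic(predicted_cri: tuple[float, float], observed_pct: float,
                       median_pred: float | None = None) -> tuple[bool, float]:
    """(covered, |median predicted - observed|) with a closed predicted interval."""
    lo, hi = predicted_cri
    if lo > hi:
        raise ValueError("predicted CrI must be ordered")
    covered = bool(lo <= observed_pct <= hi)
    if median_pred is None:
        median_pred = 0.5 * (lo + hi)
    return covered, abs(median_pred - observed_pct)


def rank_and_select(candidates: list[ModelCandidate],
                    tie_tolerance_pct: float = 1.0) -> ModelCandidate:
    """Most parsimonious adequate model.

    Ranking: covered first, then smaller median absolute difference, then
    smaller model; differences within ``tie_tolerance_pct`` percentage points
    are treated as ties so the smaller model wins.  Deterministic in the set
    of candidates (input order never matters).
    """
    if not candidates:
        raise ValueError("no candidates to rank")

    def sort_key(c: ModelCandidate):
        return (not c.covered, round(c.median_abs_diff / tie_tolerance_pct),
                c.size, c.median_abs_diff, c.covariates)

    return min(candidates, key=sort_key)
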