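"""Pipeline configuration and orchestration.

A single master seed deterministically spawns one sub-seed per stage so any
stage can be re-run standalone with identical results; every stage's JSON
output embeds its settings and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .baseline_lifetable import WeibullLifetableModel, read_life_table
from .cohort_synthesis import CohortSpec
from .effects_meta import pool_effects_table, read_effects_csv
from .excess_mortality import simulate_excess_hr, years_of_life_lost
from .hazard_model import Coefficient, CoefficientSet
from .selection_validation import (enumerate_models, rank_and_select,
                                   read_validation_studies, simulate_study_mortality)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "cohort_spec_from_dict"]

_STAGE_OFFSETS = {"meta": 1, "baseline": 2, "synth": 3, "select": 4, "excess": 5}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def cohort_spec_from_dict(d: dict) -> CohortSpec:
    d = dict(d)
    for key in ("weight_regression", "six_mwd_regression", "severity_probs"):
        if key in d:
            d[key] = tuple(d[key])
    return CohortSpec(**d)


@dataclass
class PipelineConfig:
    """Paths and settings for a full meta -> baseline -> select -> excess run."""

    effects_csv: str
    lifetable_csv: str
    studies_csv: str
    out_dir: str = "bridgesurv_out"
    cohort_spec: dict = field(default_factory=dict)
    n_chains: int = 3
    n_iter: int = 50_000
    n_burnin: int = 25_000
    n_replicates: int = 500
    excess_n: int = 10_000
    fit_min_age: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a non-negative integer")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _write_stage(out_dir: Path, name: str, payload: dict) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{name}.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute meta -> baseline -> select -> excess, writing one JSON per stage.

    Returns the consolidated report dict; any stage failure raises with the
    stage name in the message.
    """
    out_dir = Path(config.out_dir)
    report: dict = {"version": __version__, "seed": config.seed}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # re-raise with stage context
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # --- meta ---
    def do_meta():
        effects = read_effects_csv(config.effects_csv)
        summaries = pool_effects_table(
            effects, n_chains=config.n_chains, n_iter=config.n_iter,
            n_burnin=config.n_burnin, seed=stage_seed(config.seed, "meta"))
        payload = {"stage": "meta", "seed": stage_seed(config.seed, "meta"),
                   "input_hash": _file_hash(config.effects_csv),
                   "settings": {"n_chains": config.n_chains, "n_iter": config.n_iter,
                                "n_burnin": config.n_burnin},
                   "summaries": summaries}
        _write_stage(out_dir, "meta", payload)
        return summaries

    meta = _stage("meta", do_meta)
    report["meta"] = meta

    # --- baseline ---
    def do_baseline():
        table = read_life_table(config.lifetable_csv)
        results = WeibullLifetableModel(table, fit_min_age=config.fit_min_age).fit()
        payload = {"stage": "baseline", "input_hash": _file_hash(config.lifetable_csv),
                   "settings": {"fit_min_age": config.fit_min_age},
                   "fits": results.to_dict()}
        _write_stage(out_dir, "baseline", payload)
        return results

    baselines = _stage("baseline", do_baseline)
    report["baseline"] = baselines.to_dict()

    # --- coefficients from pooled effects ---
    spec = cohort_spec_from_dict(config.cohort_spec)
    coeffs = coefficients_from_meta(meta)

    # --- selection ---
    def do_select():
        studies = read_validation_studies(config.studies_csv)
        reference = studies[0]  # single-reference-study default
        sel_seed = stage_seed(config.seed, "select")
        candidates = []
        for i, cov in enumerate(enumerate_models(tuple(sorted(coeffs.coeffs)))):
            candidates.append(simulate_study_mortality(
                cov, spec, reference, baselines, coeffs,
                n_replicates=config.n_replicates, seed=sel_seed + i))
        selected = rank_and_select(candidates)
        payload = {"stage": "select", "seed": sel_seed,
                   "input_hash": _file_hash(config.studies_csv),
                   "reference_study": reference.label,
                   "candidates": [c.to_dict() for c in candidates],
                   "selected": selected.to_dict()}
        _write_stage(out_dir, "select", payload)
        return selected

    selected = _stage("select", do_select)
    report["selected"] = selected.to_dict()

    # --- excess mortality ---
    def do_excess():
        ex_seed = stage_seed(config.seed, "excess")
        result = simulate_excess_hr(spec, coeffs,
                                    covariates=selected.covariates or ("dysphagia",),
                                    n=config.excess_n, seed=ex_seed)
        yll = years_of_life_lost(baselines, result)
        payload = {"stage": "excess", "seed": ex_seed, **result.summary(),
                   "yll_years": yll}
        _write_stage(out_dir, "excess", payload)
        return payload

    excess = _stage("excess", do_excess)
    report["excess"] = excess

    _write_stage(out_dir, "report", _round_pcts(report))
    return report


def coefficients_from_meta(meta_summaries: dict, per_metre_scale: float = 281.0,
                           n_samples: int = 2000, seed: int = 12345) -> CoefficientSet:
    """Turn pooled log-HR summaries into a CoefficientSet with normal
    posterior-approximation samples.

    The walking-distance effect is stored per metre of deficit by dividing
    the pooled log HR by ``per_metre_scale`` when the pooled estimate was
    reported per typical cohort deficit rather than per metre.
    """
    rng = np.random.default_rng(seed)
    coeffs = {}
    for pred, summ in meta_summaries.items():
        mean = summ["d_mean"]
        sd = summ["d_var"] ** 0.5
        scale = per_metre_scale if pred == "six_mwd" else 1.0
        samples = rng.normal(mean, sd, size=n_samples) / scale
        coeffs[pred] = Coefficient(point=mean / scale, samples=samples,
                                   per_unit="per metre lost" if pred == "six_mwd"
                                   else "presence")
    return CoefficientSet(coeffs)


def _round_pcts(obj):
    """Round float leaves to sensible JSON precision (percent-like to 1 dp)."""
    if isinstance(obj, dict):
        return {k: _round_pcts(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_pcts(v) for v in obj]
    if isinstance(obj, float):
        return round(obj, 6)
    return obj
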