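"""Bayesian random-effects pooling of literature hazard ratios.

Published effect sizes arrive as a hazard (or risk) ratio with a 95%
confidence interval.  Pooling happens entirely on the log scale: each study
contributes ``beta_i = log(HR_i)`` with a variance reconstructed from the
lower CI bound, and a normal-normal hierarchical model

    beta_i  ~ Normal(delta_i, Var(beta_i))
    delta_i ~ Normal(d, tau^2)

with a diffuse ``Normal(0, 1e5)`` prior on the pooled effect ``d`` and a
``Uniform[0, 10]`` prior on the between-study variance ``tau^2``.  The
posterior is explored by Gibbs sampling: ``d`` and the ``delta_i`` have
conjugate normal full conditionals, while ``tau^2`` is updated by slice
sampling within its bounded support.  Hazard-ratio summaries are obtained by
exponentiating posterior draws of ``d`` only at the reporting stage.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StudyEffect",
    "LogEffect",
    "MetaPosterior",
    "RandomEffectsMeta",
    "log_effect_from_ci",
    "fit_random_effects",
    "gelman_rubin",
    "pooled_hr_summary",
    "read_effects_csv",
    "pool_effects_table",
]

PREDICTORS = ("dysphagia", "falls", "wheelchair", "six_mwd", "aspiration_pneumonia")

TAU2_MAX = 10.0  # upper bound of the uniform prior on tau^2
D_PRIOR_VAR = 1e5  # diffuse normal prior variance on the pooled effect


class InvalidEffectError(ValueError):
    """A published effect size violates its invariants (non-positive HR/CI)."""


class SamplerFailureError(RuntimeError):
    """The MCMC chain reached a non-finite state."""


@dataclass(frozen=True)
class StudyEffect:
    """One literature hazard-ratio estimate with its 95% CI."""

    study_label: str
    predictor: str
    hr: float
    ci_lower: float
    ci_upper: float
    population_tag: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.hr) and math.isfinite(self.ci_lower) and math.isfinite(self.ci_upper)):
            raise InvalidEffectError(f"non-finite effect size in study {self.study_label!r}")
        if self.hr <= 0 or self.ci_lower <= 0:
            raise InvalidEffectError(
                f"study {self.study_label!r}: hr and ci_lower must be positive "
                f"(got hr={self.hr}, ci_lower={self.ci_lower})"
            )
        if not (self.ci_lower <= self.hr <= self.ci_upper):
            raise InvalidEffectError(
                f"study {self.study_label!r}: require ci_lower <= hr <= ci_upper"
            )


@dataclass(frozen=True)
class LogEffect:
    """Log-scale effect size beta = log(HR) with its reconstructed variance."""

    beta: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise InvalidEffectError("variance must be non-negative")


def log_effect_from_ci(effect: StudyEffect, warn_asymmetric: bool = True) -> LogEffect:
    """Reconstruct the log-effect and its variance from an HR and lower CI bound.

    ``Var(beta) = ((beta - log(ci_lower)) / 1.96)^2`` — only the lower bound
    enters; the upper bound is used solely to warn when the published interval
    is asymmetric on the log scale by more than 10%, which suggests the CI was
    not a Wald interval for log HR.
    """
    beta = math.log(effect.hr)
    half_low = beta - math.log(effect.ci_lower)
    variance = (half_low / 1.96) ** 2
    if warn_asymmetric and effect.ci_upper > effect.hr > effect.ci_lower:
        half_high = math.log(effect.ci_upper) - beta
        if abs(half_high - half_low) > 0.10 * half_low:
            warnings.warn(
                f"study {effect.study_label!r}: CI asymmetric on the log scale "
                f"(lower half-width {half_low:.3f}, upper {half_high:.3f}); "
                "variance uses the lower bound only",
                stacklevel=2,
            )
    return LogEffect(beta=beta, variance=variance)


@dataclass
class MetaPosterior:
    """MCMC draws of the pooled effect, between-study variance and study effects.

    Arrays are shaped ``(n_chains, n_kept)`` for ``d`` and ``tau2`` and
    ``(n_chains, n_kept, n_studies)`` for the per-study ``delta``; only
    post-burn-in draws are retained.
    """

    d_samples: np.ndarray
    tau2_samples: np.ndarray
    delta_samples: np.ndarray
    n_chains: int
    n_iter: int
    n_burnin: int
    rhat: dict[str, float] = field(default_factory=dict)

    @property
    def d_flat(self) -> np.ndarray:
        return self.d_samples.reshape(-1)

    @property
    def tau2_flat(self) -> np.ndarray:
        return self.tau2_samples.reshape(-1)

    def summary(self) -> pd.DataFrame:
        """Posterior summary table (log scale and HR scale) for d and tau^2."""
        d = self.d_flat
        t2 = self.tau2_flat
        rows = {
            "d": (d.mean(), d.var(ddof=1), np.median(d),
                  np.quantile(d, 0.025), np.quantile(d, 0.975), self.rhat.get("d", np.nan)),
            "tau2": (t2.mean(), t2.var(ddof=1), np.median(t2),
                     np.quantile(t2, 0.025), np.quantile(t2, 0.975), self.rhat.get("tau2", np.nan)),
        }
        return pd.DataFrame.from_dict(
            rows, orient="index",
            columns=["mean", "var", "median", "q2.5", "q97.5", "rhat"],
        )


def _slice_sample_tau2(tau2: float, ss: float, n: int, rng: np.random.Generator,
                       width: float = 0.5, max_steps: int = 50) -> float:
    """Slice-sample tau^2 from its full conditional under the Uniform[0, 10] prior.

    The conditional log-density given the current delta and d reduces to
    ``-n/2 log(tau2) - ss / (2 tau2)`` on (0, TAU2_MAX], with
    ``ss = sum (delta_i - d)^2``.  Stepping-out with shrinkage; no tuning.
    """

    def logf(t2: float) -> float:
        if t2 <= 0.0 or t2 > TAU2_MAX:
            return -np.inf
        return -0.5 * n * math.log(t2) - ss / (2.0 * t2)

    ly = logf(tau2) + math.log(rng.uniform())
    lo = tau2 - width * rng.uniform()
    hi = lo + width
    steps = max_steps
    while steps > 0 and lo > 0.0 and logf(lo) > ly:
        lo -= width
        steps -= 1
    lo = max(lo, 1e-12)
    steps = max_steps
    while steps > 0 and hi < TAU2_MAX and logf(hi) > ly:
        hi += width
        steps -= 1
    hi = min(hi, TAU2_MAX)
    while True:
        prop = rng.uniform(lo, hi)
        if logf(prop) > ly:
            return prop
        if prop < tau2:
            lo = prop
        else:
            hi = prop
        if hi - lo < 1e-14:  # degenerate slice; keep current state
            return tau2


class RandomEffectsMeta:
    """Normal-normal random-effects meta-analysis model.

    Parameters
    ----------
    effects : sequence of LogEffect or StudyEffect
        StudyEffect instances are converted via :func:`log_effect_from_ci`.

    Examples
    --------
    >>> eff = [StudyEffect("a", "dysphagia", 1.8, 1.1, 2.9, "elderly")]
    >>> res = RandomEffectsMeta(eff).fit(n_iter=2000, n_burnin=1000, seed=1)
    >>> res.pooled_hr_summary()["hr_pooled"]  # doctest: +SKIP
    """

    def __init__(self, effects) -> None:
        effects = list(effects)
        if not effects:
            raise ValueError("at least one effect is required")
        if isinstance(effects[0], StudyEffect):
            effects = [log_effect_from_ci(e, warn_asymmetric=False) for e in effects]
        self.effects: list[LogEffect] = effects
        self.beta = np.array([e.beta for e in effects], dtype=float)
        self.var = np.array([e.variance for e in effects], dtype=float)
        # zero within-study variance would make the delta_i conditional degenerate;
        # clip at a negligible floor
        self.var = np.maximum(self.var, 1e-12)

    def fit(self, n_chains: int = 3, n_iter: int = 50_000, n_burnin: int = 25_000,
            seed: int = 0, fix_tau2: float | None = None) -> "MetaResults":
        """Run the Gibbs sampler and return a results object.

        ``fix_tau2`` clamps the between-study variance (used for the
        tau^2 -> 0 shrinkage limit checks); left None for the full model.
        """
        if n_burnin >= n_iter:
            raise ValueError("n_burnin must be < n_iter")
        if n_chains < 1:
            raise ValueError("need at least one chain")
        n = self.beta.size
        n_kept = n_iter - n_burnin
        d_out = np.empty((n_chains, n_kept))
        t2_out = np.empty((n_chains, n_kept))
        delta_out = np.empty((n_chains, n_kept, n))

        inv_var = 1.0 / self.var
        for c in range(n_chains):
            rng = np.random.default_rng(int(seed) + c)
            # overdispersed but sane initial states per chain
            d = float(self.beta.mean()) + rng.normal(scale=0.5)
            tau2 = fix_tau2 if fix_tau2 is not None else float(rng.uniform(0.05, 1.0))
            delta = self.beta.copy()
            for it in range(n_iter):
                # d | beta, tau2 — partially collapsed (delta marginalised out):
                # beta_i | d ~ Normal(d, var_i + tau2), so the conditional is
                # conjugate normal and mixing stays good as tau2 -> 0
                w = 1.0 / (self.var + tau2)
                prec_d = w.sum() + 1.0 / D_PRIOR_VAR
                mean_d = float(w @ self.beta) / prec_d
                d = mean_d + rng.standard_normal() / math.sqrt(prec_d)
                # delta_i | d, beta, tau2 — conjugate normal (redrawn after d)
                prec = inv_var + 1.0 / tau2
                mean = (self.beta * inv_var + d / tau2) / prec
                delta = mean + rng.standard_normal(n) / np.sqrt(prec)
                # tau2 | rest — slice sampling within [0, 10]
                if fix_tau2 is None:
                    ss = float(np.sum((delta - d) ** 2))
                    tau2 = _slice_sample_tau2(tau2, ss, n, rng)
                if not math.isfinite(d) or not math.isfinite(tau2):
                    raise SamplerFailureError(
                        f"chain {c} reached a non-finite state at iteration {it}"
                    )
                if it >= n_burnin:
                    k = it - n_burnin
                    d_out[c, k] = d
                    t2_out[c, k] = tau2
                    delta_out[c, k] = delta

        posterior = MetaPosterior(
            d_samples=d_out, tau2_samples=t2_out, delta_samples=delta_out,
            n_chains=n_chains, n_iter=n_iter, n_burnin=n_burnin,
        )
        if n_chains >= 2:
            posterior.rhat = {
                "d": gelman_rubin(d_out),
                "tau2": gelman_rubin(t2_out),
            }
        return MetaResults(self, posterior)


class MetaResults:
    """Fitted random-effects meta-analysis: posterior draws plus summaries."""

    RHAT_THRESHOLD = 1.1

    def __init__(self, model: RandomEffectsMeta, posterior: MetaPosterior) -> None:
        self.model = model
        self.posterior = posterior

    @property
    def rhat(self) -> dict[str, float]:
        return self.posterior.rhat

    @property
    def converged(self) -> bool:
        return all(r < self.RHAT_THRESHOLD for r in self.posterior.rhat.values())

    def pooled_hr_summary(self) -> dict[str, float]:
        return pooled_hr_summary(self.posterior)

    def d_samples_flat(self) -> np.ndarray:
        return self.posterior.d_flat

    def summary(self) -> pd.DataFrame:
        return self.posterior.summary()


def fit_random_effects(effects, n_chains: int = 3, n_iter: int = 50_000,
                       n_burnin: int = 25_000, seed: int = 0,
                       fix_tau2: float | None = None) -> MetaPosterior:
    """Functional wrapper around :class:`RandomEffectsMeta`; returns the posterior."""
    res = RandomEffectsMeta(effects).fit(
        n_chains=n_chains, n_iter=n_iter, n_burnin=n_burnin, seed=seed, fix_tau2=fix_tau2
    )
    return res.posterior


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor (R-hat) from >=2 equal-length chains.

    Classic between/within form: with m chains of length n, chain means x̄_j
    and chain variances s²_j,

        W = mean(s²_j),  B/n = var(x̄_j),  V̂ = (n-1)/n · W + B/n,
        R-hat = sqrt(V̂ / W), floored at 1 (no between-chain dispersion
        cannot indicate a scale reduction below 1).
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need >=2 chains of equal length")
    m, n = arr.shape
    if n < 2:
        raise ValueError("chains must have length >=2")
    chain_means = arr.mean(axis=1)
    w = arr.var(axis=1, ddof=1).mean()
    b_over_n = chain_means.var(ddof=1)
    if w == 0.0:
        return 1.0 if b_over_n == 0.0 else np.inf
    v_hat = (n - 1) / n * w + b_over_n
    return max(float(np.sqrt(v_hat / w)), 1.0)


def pooled_hr_summary(posterior: MetaPosterior) -> dict[str, float]:
    """Hazard-ratio summary of the pooled effect.

    ``hr_pooled`` is exp(posterior mean of d) (the convention used for the
    headline pooled HR); exp(median) is also reported.  The 95% CrI is the
    equal-tailed interval of exp(d).
    """
    d = posterior.d_flat
    if d.size == 0:
        raise ValueError("empty posterior")
    t2 = posterior.tau2_flat
    return {
        "d_mean": float(d.mean()),
        "d_var": float(d.var(ddof=1)) if d.size > 1 else 0.0,
        "d_median": float(np.median(d)),
        "tau2_median": float(np.median(t2)),
        "hr_pooled": float(np.exp(d.mean())),
        "hr_median": float(np.exp(np.median(d))),
        "cri_low": float(np.exp(np.quantile(d, 0.025))),
        "cri_high": float(np.exp(np.quantile(d, 0.975))),
        "rhat": float(posterior.rhat.get("d", np.nan)),
    }


def read_effects_csv(path) -> list[StudyEffect]:
    """Read a literature-effects table with columns
    study_label,predictor,hr,ci_lower,ci_upper,population_tag."""
    df = pd.read_csv(path)
    required = {"study_label", "predictor", "hr", "ci_lower", "ci_upper"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"effects CSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(StudyEffect(
            study_label=str(row.study_label),
            predictor=str(row.predictor),
            hr=float(row.hr),
            ci_lower=float(row.ci_lower),
            ci_upper=float(row.ci_upper),
            population_tag=str(getattr(row, "population_tag", "")),
        ))
    return out


def pool_effects_table(effects: list[StudyEffect], n_chains: int = 3,
                       n_iter: int = 50_000, n_burnin: int = 25_000,
                       seed: int = 0) -> dict[str, dict]:
    """Pool each predictor's studies separately; returns predictor -> summary."""
    by_pred: dict[str, list[StudyEffect]] = {}
    for e in effects:
        by_pred.setdefault(e.predictor, []).append(e)
    out = {}
    for i, (pred, group) in enumerate(sorted(by_pred.items())):
        res = RandomEffectsMeta(group).fit(
            n_chains=n_chains, n_iter=n_iter, n_burnin=n_burnin,
            seed=int(seed) + 1000 * i,
        )
        summ = res.pooled_hr_summary()
        summ["n_studies"] = len(group)
        out[pred] = summ
    return out


def write_meta_json(summaries: dict[str, dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(summaries, fh, indent=2)
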