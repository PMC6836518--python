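"""Random-effects pooling: variance reconstruction, Gibbs sampler, R-hat."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bridgesurv.effects_meta import (InvalidEffectError, LogEffect,
                                     RandomEffectsMeta, StudyEffect,
                                     fit_random_effects, gelman_rubin,
                                     log_effect_from_ci, pool_effects_table,
                                     pooled_hr_summary, read_effects_csv)


@pytest.mark.parametrize("hr,ci_lower,beta,variance", [
    (1.0, math.exp(-1.96), 0.0, 1.0),         # unit-variance case
    (2.0, 1.2, 0.6931472, 0.0679256),          # hand computation
    (1.72, 0.81, 0.5423243, 0.1476149),        # pooled-summary example
])
def test_log_effect_from_ci(hr, ci_lower, beta, variance):
    eff = StudyEffect("s", "dysphagia", hr, ci_lower, max(hr, 4.0), "tag")
    le = log_effect_from_ci(eff, warn_asymmetric=False)
    assert le.beta == pytest.approx(beta, abs=1e-6)
    assert le.variance == pytest.approx(variance, abs=1e-6)


@pytest.mark.parametrize("hr,lo,hi", [(-1.0, 0.5, 2.0), (0.0, 0.5, 2.0),
                                      (1.5, -0.1, 2.0), (1.5, 0.0, 2.0)])
def test_invalid_effects_rejected(hr, lo, hi):
    with pytest.raises(InvalidEffectError):
        StudyEffect("s", "dysphagia", hr, lo, hi)


def test_ci_ordering_enforced():
    with pytest.raises(InvalidEffectError):
        StudyEffect("s", "dysphagia", 1.0, 1.5, 2.0)  # lower bound above hr


def test_asymmetric_ci_warns():
    with pytest.warns(UserWarning, match="asymmetric"):
        log_effect_from_ci(StudyEffect("s", "dysphagia", 2.0, 1.5, 5.0))


@given(hr=st.floats(0.1, 50.0), rel_lo=st.floats(0.05, 0.95),
       factor=st.floats(0.1, 10.0))
@settings(deadline=None, max_examples=100, derandomize=True)
def test_variance_scale_invariant(hr, rel_lo, factor):
    """Rescaling HR and CI by a common factor leaves the variance unchanged
    (it depends only on the log-ratio of HR to the lower bound)."""
    lo = hr * rel_lo
    base = log_effect_from_ci(
        StudyEffect("s", "falls", hr, lo, hr * 2, ""), warn_asymmetric=False)
    scaled = log_effect_from_ci(
        StudyEffect("s", "falls", hr * factor, lo * factor, hr * factor * 2, ""),
        warn_asymmetric=False)
    assert scaled.variance == pytest.approx(base.variance, rel=1e-9)


def test_single_study_shrinkage_limit():
    """With tau^2 clamped near 0 the pooled mean collapses to the study effect."""
    res = RandomEffectsMeta([LogEffect(0.5, 0.04)]).fit(
        n_chains=2, n_iter=4000, n_burnin=2000, seed=3, fix_tau2=1e-8)
    assert res.posterior.d_flat.mean() == pytest.approx(0.5, abs=0.02)


def test_fixed_tau2_matches_conjugate_closed_form():
    """Independent oracle: with tau^2 fixed the model is linear-Gaussian and
    the marginal posterior mean of d is a precision-weighted average."""
    rng = np.random.default_rng(5)
    betas = rng.normal(0.4, 0.25, size=12)
    variances = rng.uniform(0.02, 0.2, size=12)
    tau2 = 0.09
    effects = [LogEffect(float(b), float(v)) for b, v in zip(betas, variances)]
    res = RandomEffectsMeta(effects).fit(n_chains=3, n_iter=8000, n_burnin=4000,
                                         seed=11, fix_tau2=tau2)
    w = 1.0 / (variances + tau2)
    prec = w.sum() + 1.0 / 1e5
    closed_form = float((w * betas).sum() / prec)
    assert res.posterior.d_flat.mean() == pytest.approx(closed_form, abs=0.01)


def test_equal_variance_limit_is_arithmetic_mean():
    """tau^2 -> 0 with equal within-study variances: d -> mean of the betas."""
    betas = [0.1, 0.3, 0.5, 0.7, 0.2]
    effects = [LogEffect(b, 0.05) for b in betas]
    res = RandomEffectsMeta(effects).fit(n_chains=2, n_iter=6000, n_burnin=3000,
                                         seed=7, fix_tau2=1e-10)
    assert res.posterior.d_flat.mean() == pytest.approx(np.mean(betas), abs=0.015)


def test_tau2_prior_support_is_hard():
    rng = np.random.default_rng(1)
    effects = [LogEffect(float(rng.normal(0, 3)), 0.01) for _ in range(8)]
    post = fit_random_effects(effects, n_chains=2, n_iter=4000, n_burnin=2000, seed=9)
    assert np.all(post.tau2_flat >= 0.0)
    assert np.all(post.tau2_flat <= 10.0)


def test_sampler_reproducible():
    effects = [LogEffect(0.4, 0.05), LogEffect(0.6, 0.08), LogEffect(0.2, 0.03)]
    p1 = fit_random_effects(effects, n_chains=2, n_iter=3000, n_burnin=1500, seed=42)
    p2 = fit_random_effects(effects, n_chains=2, n_iter=3000, n_burnin=1500, seed=42)
    np.testing.assert_array_equal(p1.d_samples, p2.d_samples)
    np.testing.assert_array_equal(p1.tau2_samples, p2.tau2_samples)


def test_empty_effects_rejected():
    with pytest.raises(ValueError):
        RandomEffectsMeta([])


def test_burnin_must_be_smaller():
    with pytest.raises(ValueError):
        RandomEffectsMeta([LogEffect(0.1, 0.1)]).fit(n_iter=100, n_burnin=100)


class TestGelmanRubin:
    def test_identical_chains(self):
        chain = np.random.default_rng(0).normal(size=500)
        assert gelman_rubin([chain, chain]) == pytest.approx(1.0, abs=1e-12)

    def test_separated_chains(self):
        rng = np.random.default_rng(0)
        assert gelman_rubin([rng.normal(0, 1, 500),
                             rng.normal(100, 1, 500)]) > 10.0

    def test_stationary_chains_converge(self):
        rng = np.random.default_rng(3)
        chains = rng.normal(size=(3, 25_000))
        assert gelman_rubin(chains) < 1.05

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin([np.arange(10.0)])

    def test_agrees_with_arviz_on_stationary_chains(self):
        """Independent oracle: arviz's rank-normalised split R-hat and the
        classic form agree near 1 for well-mixed chains."""
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(8)
        chains = rng.normal(size=(4, 2000))
        ours = gelman_rubin(chains)
        theirs = float(arviz.rhat(chains))
        assert ours == pytest.approx(theirs, abs=0.01)


class TestPooledSummary:
    def test_degenerate_posterior(self):
        from bridgesurv.effects_meta import MetaPosterior
        post = MetaPosterior(d_samples=np.zeros((2, 100)),
                             tau2_samples=np.zeros((2, 100)),
                             delta_samples=np.zeros((2, 100, 1)),
                             n_chains=2, n_iter=200, n_burnin=100)
        s = pooled_hr_summary(post)
        assert s["hr_median"] == pytest.approx(1.0)
        assert s["cri_low"] == pytest.approx(1.0)
        assert s["cri_high"] == pytest.approx(1.0)

    def test_lognormal_closed_form(self):
        """d ~ N(0.7, 0.1^2): HR quantiles follow the lognormal closed form."""
        from bridgesurv.effects_meta import MetaPosterior
        rng = np.random.default_rng(10)
        d = rng.normal(0.7, 0.1, size=(2, 100_000))
        post = MetaPosterior(d_samples=d, tau2_samples=np.full_like(d, 0.01),
                             delta_samples=d[..., None], n_chains=2,
                             n_iter=200_000, n_burnin=100_000)
        s = pooled_hr_summary(post)
        assert s["hr_median"] == pytest.approx(math.exp(0.7), rel=0.01)
        assert s["cri_low"] == pytest.approx(math.exp(0.7 - 1.96 * 0.1), rel=0.01)
        assert s["cri_high"] == pytest.approx(math.exp(0.7 + 1.96 * 0.1), rel=0.01)


def test_read_and_pool_effects_csv(effects_csv):
    effects = read_effects_csv(effects_csv)
    assert len(effects) == 6
    summaries = pool_effects_table(effects, n_chains=2, n_iter=3000,
                                   n_burnin=1500, seed=0)
    assert set(summaries) == {"dysphagia", "six_mwd", "falls"}
    dys = summaries["dysphagia"]
    assert dys["n_studies"] == 4
    assert dys["cri_low"] < dys["hr_pooled"] < dys["cri_high"]
    # pooled estimate sits inside the convex hull of the study HRs
    assert 1.0 < dys["hr_pooled"] < 2.5
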