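"""Priors, likelihood, sampler and diagnostics."""

import math

import numpy as np
import pytest
from scipy import stats

from nrf2pk.bayes import (LikelihoodSpec, PriorSpec, gelman_rubin,
                          log_likelihood, log_prior, mc_sensitivity,
                          metropolis_sample)


@pytest.fixture
def priors_2d():
    return {
        "a": PriorSpec("a", "lognormal", median=2.0, gsd=3.0),
        "b": PriorSpec("b", "lognormal", median=10.0, gsd=1.5),
    }


def test_prior_density_matches_scipy_product():
    """Mixed vector against brute-force density-product evaluation."""
    priors = {
        "u": PriorSpec("u", "uniform", lower=0.0, upper=0.95),
        "lu": PriorSpec("lu", "loguniform", lower=1e-2, upper=20.0),
        "ln": PriorSpec("ln", "lognormal", median=5.0, gsd=3.0),
    }
    theta = {"u": 0.3, "lu": 0.7, "ln": 11.0}
    expected = (stats.uniform.logpdf(0.3, 0, 0.95)
                + stats.loguniform.logpdf(0.7, 1e-2, 20.0)
                + stats.lognorm.logpdf(11.0, s=math.log(3.0),
                                       scale=5.0))
    assert log_prior(theta, priors) == pytest.approx(expected, rel=1e-12)


def test_prior_outside_support_is_minus_inf():
    priors = {"u": PriorSpec("u", "uniform", lower=0.0, upper=1.0)}
    assert log_prior({"u": 1.5}, priors) == -math.inf


def test_lognormal_prior_peaks_at_median_in_log_space():
    """The density of ln(x) is maximal at the median."""
    p = PriorSpec("x", "lognormal", median=7.0, gsd=3.0)
    # log-space density: logpdf(x) + log(x)
    at = lambda x: p.logpdf(x) + math.log(x)
    assert at(7.0) > at(5.0) and at(7.0) > (at(9.0))
    assert p.logpdf(7.0) == pytest.approx(
        -math.log(7.0 * math.log(3.0) * math.sqrt(2 * math.pi)), rel=1e-12)


def test_likelihood_matches_closed_form_single_point():
    lik = LikelihoodSpec({"medium": 0.25})
    obs, pred = 120.0, 100.0
    got = log_likelihood([obs], [pred], ["medium"], lik)
    z = (math.log(obs) - math.log(pred)) / 0.25
    expected = -math.log(obs * 0.25 * math.sqrt(2 * math.pi)) - z * z / 2
    assert got == pytest.approx(expected, rel=1e-12)


def test_perfect_fit_is_likelihood_maximum():
    lik = LikelihoodSpec({"m": 0.3})
    obs = np.array([5.0, 50.0, 500.0])
    best = log_likelihood(obs, obs, ["m"] * 3, lik)
    for factor in (0.8, 1.3, 2.0):
        assert log_likelihood(obs, obs * factor, ["m"] * 3, lik) < best


def test_widening_error_never_helps_a_perfect_fit():
    obs = np.array([10.0])
    tight = log_likelihood(obs, obs, ["m"], LikelihoodSpec({"m": 0.1}))
    wide = log_likelihood(obs, obs, ["m"], LikelihoodSpec({"m": 0.2}))
    assert wide < tight


def test_likelihood_rejects_non_positive_values():
    lik = LikelihoodSpec({"m": 0.2})
    with pytest.raises(ValueError):
        log_likelihood([0.0], [1.0], ["m"], lik)
    with pytest.raises(ValueError):
        log_likelihood([1.0], [-1.0], ["m"], lik)


# --- Gelman-Rubin -----------------------------------------------------------

def test_gelman_rubin_matches_hand_formula():
    chains = np.array([[1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10],
                       [2.0, 3, 4, 5, 6, 7, 8, 9, 10, 11.0]])
    m, n = chains.shape
    W = chains.var(axis=1, ddof=1).mean()
    B = n * chains.mean(axis=1).var(ddof=1)
    expected = math.sqrt(((n - 1) / n * W + B / n) / W)
    assert gelman_rubin(chains) == pytest.approx(expected, rel=1e-12)


def test_gelman_rubin_limits():
    rng = np.random.default_rng(0)
    same = rng.standard_normal((4, 5000))
    assert gelman_rubin(same) == pytest.approx(1.0, abs=0.01)
    disjoint = np.vstack([rng.standard_normal(200),
                          rng.standard_normal(200) + 50.0])
    assert gelman_rubin(disjoint) > 10.0


def test_gelman_rubin_input_validation():
    with pytest.raises(ValueError):
        gelman_rubin(np.ones((1, 100)))


# --- Metropolis sampler -----------------------------------------------------

def test_sampler_recovers_2d_lognormal_target(priors_2d):
    """Prior-only sampling of a known 2-D lognormal reproduces its
    geometric means and geometric SDs within Monte Carlo error."""
    samples = metropolis_sample(lambda th: log_prior(th, priors_2d),
                                priors_2d, n_chains=2, n_iter=10_000,
                                thin=2, seed=3)
    for name, spec in priors_2d.items():
        x = samples.draws[name].to_numpy()
        gm = math.exp(np.mean(np.log(x)))
        gsd = math.exp(np.std(np.log(x)))
        assert gm == pytest.approx(spec.median, rel=0.1)
        assert gsd == pytest.approx(spec.gsd, rel=0.1)


def test_sampler_is_deterministic_given_seed(priors_2d):
    kw = dict(n_chains=2, n_iter=1500, thin=3, seed=11)
    a = metropolis_sample(lambda th: log_prior(th, priors_2d), priors_2d, **kw)
    b = metropolis_sample(lambda th: log_prior(th, priors_2d), priors_2d, **kw)
    assert a.draws.equals(b.draws)


def test_componentwise_update_targets_same_distribution(priors_2d):
    samples = metropolis_sample(lambda th: log_prior(th, priors_2d),
                                priors_2d, n_chains=2, n_iter=6000, thin=2,
                                seed=5, update="component")
    x = samples.draws["a"].to_numpy()
    assert math.exp(np.mean(np.log(x))) == pytest.approx(2.0, rel=0.15)


def test_uniform_prior_quantiles_reproduced():
    """Posterior equals prior when the likelihood is constant."""
    priors = {"k3": PriorSpec("k3", "uniform", lower=0.0, upper=0.95)}
    samples = metropolis_sample(lambda th: log_prior(th, priors), priors,
                                n_chains=2, n_iter=20_000, thin=4, seed=9)
    x = samples.draws["k3"].to_numpy()
    for q in (0.1, 0.25, 0.5, 0.75, 0.9):
        assert np.quantile(x, q) == pytest.approx(0.95 * q, abs=0.03)


def test_stationary_distribution_chi2(priors_2d):
    """Discretized 1-D check of detailed balance: the empirical stationary
    distribution matches the target (chi-square not rejecting at 1%)."""
    priors = {"x": PriorSpec("x", "lognormal", median=1.0, gsd=2.0)}
    samples = metropolis_sample(lambda th: log_prior(th, priors), priors,
                                n_chains=2, n_iter=100_000, thin=40, seed=2)
    z = np.log(samples.draws["x"].to_numpy()) / math.log(2.0)
    edges = stats.norm.ppf(np.linspace(0, 1, 21))
    counts, _ = np.histogram(z, bins=edges)
    chi2, pval = stats.chisquare(counts)
    assert pval > 0.01


def test_all_rejecting_posterior_raises():
    priors = {"x": PriorSpec("x", "uniform", lower=0.0, upper=1.0)}
    with pytest.raises(RuntimeError):
        metropolis_sample(lambda th: -math.inf, priors, n_chains=2,
                          n_iter=200, seed=0)


# --- Monte Carlo sensitivity ------------------------------------------------

def test_sensitivity_linear_toy_model():
    """y = 3a + b with equal priors: a dominates, an inert parameter
    scores ~0, and the identity output ranks its own parameter first."""
    priors = {n: PriorSpec(n, "uniform", lower=0.0, upper=1.0)
              for n in ("a", "b", "inert")}
    table = mc_sensitivity(lambda th: {"y": 3 * th["a"] + th["b"],
                                       "ident": th["a"]},
                           priors, n_samples=400, seed=1)
    assert table.loc["a", "y"] > table.loc["b", "y"]
    assert table.loc["inert", "importance"] < 0.15
    assert table.loc["a", "rank"] == 1
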