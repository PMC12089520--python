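"""Posterior engine: transforms, quadrature correctness, conjugate model, PESS."""

import numpy as np
import pytest
from scipy.special import ndtr
from scipy.stats import beta as beta_dist
from scipy.stats import binom, norm

from todo_design import (DLMHyperparams, NumericalError, QuadratureSettings,
                         TrialData, bb_pair_probs, bb_posterior, dlm_posterior,
                         get_tables, prior_pess, probit, probit_inv)

from conftest import DELTA1, P0


@pytest.mark.parametrize("p, x", [(0.5, 0.0), (0.2, -0.8416)])
def test_probit_known_values(p, x):
    assert probit(p) == pytest.approx(x, abs=5e-5)
    assert probit_inv(x) == pytest.approx(p, abs=5e-5)


def test_probit_roundtrip_and_domain():
    for p in (1e-6, 0.3, 0.999):
        assert probit_inv(probit(p)) == pytest.approx(p, abs=1e-12)
    with pytest.raises(ValueError):
        probit(0.0)
    with pytest.raises(ValueError):
        probit(1.0)


def test_trial_data_validation():
    with pytest.raises(ValueError):
        TrialData(y1=5, n1=4, y2=0, n2=4)
    with pytest.raises(ValueError):
        TrialData(y1=0, n1=4, y2=0, n2=4, t2=5)


def test_no_data_returns_prior(tables):
    """With no observations the reported exceedance is the prior probability.

    The prior mean of mu_j equals probit(p0) for both doses (the increment
    prior is centered), so Pr(p_j > p0) is exactly 1/2 a priori.
    """
    s = tables.summary(TrialData(0, 0, 0, 0))
    assert s.pr_exceed[0] == pytest.approx(0.5, abs=1e-3)
    assert s.pr_exceed[1] == pytest.approx(0.5, abs=1e-3)


def test_pooled_limit_small_tau():
    """As tau -> 0 the two doses share one probit parameter.

    Oracle: dense 1-D quadrature of the single-parameter model fitted to
    the pooled counts, written independently of the table engine.
    """
    hp = DLMHyperparams(theta=probit(P0), sigma1=3.0, tau=1e-6)
    tab = get_tables(hp, P0, DELTA1)
    y1, n1, y2, n2 = 3, 10, 6, 10
    s = tab.summary(TrialData(y1, n1, y2, n2))

    mu = np.linspace(-12, 12, 20001)
    p = ndtr(mu)
    post = norm.pdf(mu, hp.theta, hp.sigma1) * binom.pmf(y1 + y2, n1 + n2, p)
    post /= np.trapezoid(post, mu)
    pr = np.trapezoid(post * (p > P0), mu)
    mean = np.trapezoid(post * p, mu)
    assert s.pr_exceed[0] == pytest.approx(pr, abs=2e-3)
    assert s.pr_exceed[1] == pytest.approx(pr, abs=2e-3)
    assert s.post_mean[0] == pytest.approx(mean, abs=2e-3)
    assert s.post_mean[1] == pytest.approx(mean, abs=2e-3)


def _single_dose_oracle(hp, y, n, p0):
    """Independent one-parameter probit posterior, with analytic handling of
    the flat prior's tails (p pinned at 0/1 beyond the grid)."""
    mu = np.linspace(-8, 8, 4001)
    p = ndtr(mu)
    w = norm.pdf(mu, hp.theta, hp.sigma1) * binom.pmf(y, n, p)
    lo = norm.cdf(-8, hp.theta, hp.sigma1) * (1.0 if y == 0 else 0.0)
    hi = norm.sf(8, hp.theta, hp.sigma1) * (1.0 if y == n else 0.0)
    z = np.trapezoid(w, mu) + lo + hi
    pr = (np.trapezoid(w * (p > p0), mu) + hi) / z
    mean = (np.trapezoid(w * p, mu) + hi) / z
    return pr, mean


def test_independence_with_large_scales():
    """With tau = sigma1 = 50 the doses behave like single-dose posteriors.

    Checked where decoupling genuinely holds: when the other arm carries no
    data (exact, for any tau -- the neighbor integrates out of the joint),
    and when the two arms' data are concordant.  Discordant arms are
    excluded deliberately: the heavy-tailed increment prior lets strongly
    contrasting likelihoods re-weight the small-sigma2 (coupled) component,
    so full independence is never reached there -- that adaptive borrowing
    is the model's point, and the quadrature value is confirmed against
    MCMC in the backend-agreement battery.
    """
    hp = DLMHyperparams(theta=probit(P0), sigma1=50.0, tau=50.0)
    tab = get_tables(hp, P0, DELTA1)

    # neighbor arm empty: dose-1 marginal is exactly the single-dose model
    for y1 in (0, 3, 10):
        s = tab.summary(TrialData(y1, 10, 0, 0))
        pr1, m1 = _single_dose_oracle(hp, y1, 10, P0)
        assert s.pr_exceed[0] == pytest.approx(pr1, abs=0.005)
        assert s.post_mean[0] == pytest.approx(m1, abs=0.005)

    # symmetric arms: coupling has nothing to pool, so marginals decouple
    # (even a one-responder asymmetry measurably sharpens both posteriors)
    for (y1, y2) in [(5, 5), (10, 10), (2, 2)]:
        s = tab.summary(TrialData(y1, 10, y2, 10))
        pr1, m1 = _single_dose_oracle(hp, y1, 10, P0)
        pr2, m2 = _single_dose_oracle(hp, y2, 10, P0)
        assert s.pr_exceed[0] == pytest.approx(pr1, abs=0.01)
        assert s.pr_exceed[1] == pytest.approx(pr2, abs=0.01)
        assert s.post_mean[0] == pytest.approx(m1, abs=0.01)
        assert s.post_mean[1] == pytest.approx(m2, abs=0.01)


def test_monotone_in_responders(tables):
    """Pr(p1 > p0 | D) never decreases in y1 over the full n=10 grid."""
    t = tables.table(10, 10)
    assert np.all(np.diff(t["pr1"], axis=0) >= -1e-12)
    assert np.all(np.diff(t["pr2"], axis=1) >= -1e-12)


def test_pp_ni_monotone_in_margin(hyper):
    """Pr(p2 - p1 < delta | D) is non-decreasing in the margin delta."""
    t5 = get_tables(hyper, P0, 0.05).table(10, 10)["pp_ni"]
    t10 = get_tables(hyper, P0, 0.10).table(10, 10)["pp_ni"]
    assert np.all(t10 - t5 >= -1e-12)
    assert np.all((t5 >= 0) & (t5 <= 1))


def test_refinement_check_raises_on_unmet_tolerance(hyper):
    coarse = QuadratureSettings(mu_step=0.8, sigma_nodes=4, tol=1e-9)
    with pytest.raises(NumericalError):
        dlm_posterior(TrialData(4, 10, 6, 10), hyper, P0, DELTA1,
                      settings=coarse, check=True)


# -- conjugate beta-binomial ------------------------------------------------

def test_bb_posterior_closed_form():
    # uniform prior, no data: Pr(p > 0.2) is the uniform tail
    b = bb_posterior(0, 0, 0.2, prior=(1.0, 1.0))
    assert b.pr_exceed == pytest.approx(0.8, abs=1e-12)
    # y = n: posterior mean (p0 + n)/(1 + n), strictly increasing in n
    means = [bb_posterior(n, n, 0.2).post_mean for n in (1, 5, 20)]
    assert means == sorted(means)
    assert means[1] == pytest.approx((0.2 + 5) / 6, abs=1e-12)


def test_bb_exceedance_vs_sampling_oracle():
    b = bb_posterior(4, 10, 0.2)
    rng = np.random.default_rng(123)
    draws = rng.beta(b.a, b.b, 1_000_000)
    mc = np.mean(draws > 0.2)
    se = np.sqrt(mc * (1 - mc) / draws.size)
    assert abs(b.pr_exceed - mc) < 3 * se


def test_bb_pair_vs_sampling_oracle():
    rng = np.random.default_rng(7)
    out = bb_pair_probs(4, 10, 7, 10, 0.2, delta1=0.05)
    a1, b1 = 0.2 + 4, 0.8 + 6
    a2, b2 = 0.2 + 7, 0.8 + 3
    s1 = rng.beta(a1, b1, 1_000_000)
    s2 = rng.beta(a2, b2, 1_000_000)
    for key, event in (("pp_ni", s2 - s1 < 0.05), ("pr_greater", s2 > s1)):
        mc = event.mean()
        se = np.sqrt(mc * (1 - mc) / s1.size)
        assert abs(out[key] - mc) < max(3 * se, 1e-3)


# -- prior effective sample size --------------------------------------------

def test_pess_uniform_prior_is_two():
    """Phi(N(0,1)) is exactly Uniform(0,1), whose Beta match is Beta(1,1)."""
    hp = DLMHyperparams(theta=0.0, sigma1=1.0)
    assert prior_pess(hp, 1) == pytest.approx(2.0, abs=0.01)


def test_pess_default_specification(hyper):
    """Moment-matched PESS under the default vague prior.

    The sigma1 = 3 prior is strongly dispersed on the probability scale, so
    both doses carry well under one phantom patient of information, with
    the second dose (extra half-Cauchy increment) even vaguer; both sit
    inside the (0.01, 4) noninformativeness band.
    """
    d1 = prior_pess(hyper, 1)
    d2 = prior_pess(hyper, 2)
    assert d1 == pytest.approx(0.41, abs=0.02)
    assert d2 == pytest.approx(0.32, abs=0.02)
    assert d2 < d1 < 1.0
    assert 0.01 < d2 < 4.0
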