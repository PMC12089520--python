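"""Posterior engine for the two-dose Bayesian dynamic linear model.

The dose-response model ties the two doses together on the probit scale:

    y_j | p_j        ~ Binomial(n_j, p_j),          j = 1, 2
    mu_j = probit(p_j)
    mu_1             ~ Normal(theta, sigma1^2)
    mu_2 | mu_1      ~ Normal(mu_1, sigma2^2)
    sigma2           ~ HalfCauchy(xi, tau)           (support sigma2 > xi)

The half-Cauchy scale on the increment lets the model shrink the two dose
effects toward each other when the data look similar, while its heavy tail
releases the shrinkage when they do not.

All posterior quantities used by the design -- Pr(p_j > p0 | D),
PP_NI = Pr(p2 - p1 < delta1 | D) and posterior means -- are computed by
deterministic quadrature: the half-Cauchy layer is integrated exactly under
the substitution sigma2 = xi + tau * tan(pi*u/2) (which maps the half-Cauchy
to Uniform(0,1)), and the (mu1, mu2) plane is discretized on a cell grid with
exact normal cell masses plus two analytic tail cells per axis at p = 0 and
p = 1, so the heavy prior tails are never truncated.  A seeded random-walk
MCMC backend is provided as an independent cross-check.

A conjugate beta-binomial model (used by the comparator designs) and the
prior effective sample size (PESS) diagnostic live here as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import log_ndtr, ndtr, ndtri, owens_t
from scipy.stats import beta as beta_dist
from scipy.stats import binom

__all__ = [
    "DLMHyperparams",
    "TrialData",
    "PosteriorSummary",
    "QuadratureSettings",
    "NumericalError",
    "DLMTables",
    "probit",
    "probit_inv",
    "dlm_posterior",
    "dlm_posterior_mcmc",
    "bb_posterior",
    "bb_pair_probs",
    "BBTables",
    "get_bb_tables",
    "prior_pess",
    "get_tables",
]


class NumericalError(RuntimeError):
    """Raised when a posterior integration fails its self-consistency check."""


# ---------------------------------------------------------------------------
# probit transform
# ---------------------------------------------------------------------------

def probit(p):
    """Probit transform Phi^{-1}(p); domain (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("probit requires 0 < p < 1")
    out = ndtri(p)
    return float(out) if out.ndim == 0 else out


def probit_inv(x):
    """Inverse probit Phi(x)."""
    out = ndtr(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DLMHyperparams:
    """Hyperparameters of the dynamic linear model prior.

    theta   : prior mean of mu_1 (probit scale); conventionally probit(p0).
    sigma1  : prior SD of mu_1; large values (>= 2) keep the prior vague.
    xi      : half-Cauchy location of sigma2 (default 0).
    tau     : half-Cauchy scale of sigma2 (default 1); larger tau weakens
              the between-dose shrinkage.
    """

    theta: float
    sigma1: float = 3.0
    xi: float = 0.0
    tau: float = 1.0

    def __post_init__(self):
        if not self.sigma1 > 0:
            raise ValueError("sigma1 must be positive")
        if not self.tau > 0:
            raise ValueError("tau must be positive")

    @classmethod
    def default_for(cls, p0: float) -> "DLMHyperparams":
        """Default specification theta = probit(p0), sigma1 = 3, xi = 0, tau = 1."""
        return cls(theta=probit(p0))


@dataclass(frozen=True)
class TrialData:
    """Accumulated per-dose counts at an analysis stage.

    y1, n1, y2, n2 are responder counts and evaluable patients for the lower
    and higher dose.  Counts for a dose dropped at the interim still enter
    the joint posterior at later analyses.  Optional toxicity counts t1, t2
    (out of the same n1, n2) support the co-primary extension.
    """

    y1: int
    n1: int
    y2: int
    n2: int
    stage: int = 2
    t1: int | None = None
    t2: int | None = None

    def __post_init__(self):
        for y, n, lab in ((self.y1, self.n1, "1"), (self.y2, self.n2, "2")):
            if not (0 <= y <= n):
                raise ValueError(f"need 0 <= y{lab} <= n{lab}")
        for t, n, lab in ((self.t1, self.n1, "1"), (self.t2, self.n2, "2")):
            if t is not None and not (0 <= t <= n):
                raise ValueError(f"need 0 <= t{lab} <= n{lab}")
        if self.stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior quantities for one outcome table."""

    pr_exceed: tuple[float, float]     # Pr(p_j > p0 | D)
    pp_ni: float | None                # Pr(p2 - p1 < delta1 | D)
    post_mean: tuple[float, float]     # E[p_j | D]
    method: str = "quadrature"
    tol: float = 1e-3


@dataclass(frozen=True)
class QuadratureSettings:
    """Grid resolution for the deterministic posterior integration.

    mu_max  : half-width of the interior probit grid; beyond +-mu_max the
              response probability is 0/1 to ~1e-15 and is handled by the
              analytic tail cells.
    mu_step : cell width on the probit scale.
    sigma_nodes : Gauss-Legendre nodes for the half-Cauchy layer.
    tol     : tolerance for the optional refinement self-check.
    """

    mu_max: float = 8.0
    mu_step: float = 0.05
    sigma_nodes: int = 48
    tol: float = 1e-3


# ---------------------------------------------------------------------------
# quadrature engine
# ---------------------------------------------------------------------------

class DLMTables:
    """Cached posterior tables for the two-dose DLM.

    One instance fixes (hyper, p0, delta1, settings) and serves posterior
    summaries for any outcome table (y1, n1, y2, n2) as vectorized arrays
    over the full (y1, y2) grid.  The expensive part -- the prior cell
    masses and the half-Cauchy-mixed transition kernel -- is built once;
    each (n1, n2) table then costs a handful of small matrix products, so
    exact enumeration of whole trial designs is cheap.
    """

    def __init__(self, hyper: DLMHyperparams, p0: float,
                 delta1: float | None = None,
                 settings: QuadratureSettings = QuadratureSettings()):
        if not 0.0 < p0 < 1.0:
            raise ValueError("p0 must be in (0, 1)")
        self.hyper = hyper
        self.p0 = float(p0)
        self.delta1 = None if delta1 is None else float(delta1)
        self.settings = settings
        self._tables: dict[tuple[int, int], dict[str, np.ndarray]] = {}
        self._build_grid()

    def _build_grid(self):
        s = self.settings
        hp = self.hyper
        L, h = s.mu_max, s.mu_step
        n_cells = int(round(2 * L / h))
        edges = -L + h * np.arange(n_cells + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        # node response probabilities, with exact 0/1 tail nodes
        p_all = np.concatenate(([0.0], ndtr(centers), [1.0]))
        self._edges, self._centers, self._h = edges, centers, h
        self.p_nodes = p_all
        G = n_cells + 2

        # prior cell masses for mu1 ~ N(theta, sigma1^2), tails exact
        z = (edges - hp.theta) / hp.sigma1
        cdf = ndtr(z)
        prior1 = np.empty(G)
        prior1[0] = cdf[0]
        prior1[1:-1] = np.diff(cdf)
        prior1[-1] = 1.0 - cdf[-1]

        # transition kernel mixed over the half-Cauchy scale:
        # sigma = xi + tau tan(pi u / 2) maps HC(xi, tau) to Uniform(0,1) in u
        un, uw = leggauss(s.sigma_nodes)
        u = 0.5 * (un + 1.0)
        w = 0.5 * uw
        M = np.zeros((G, G))
        for ui, wi in zip(u, w):
            sig = hp.xi + hp.tau * np.tan(0.5 * np.pi * ui)
            zz = (edges[None, :] - centers[:, None]) / sig
            cdfz = ndtr(zz)
            M[1:-1, 0] += wi * cdfz[:, 0]
            M[1:-1, 1:-1] += wi * np.diff(cdfz, axis=1)
            M[1:-1, -1] += wi * (1.0 - cdfz[:, -1])
        # tail mu1 cells: the kernel mass stays in the same tail (the spill
        # back into the interior is O(1 - Phi(mu_max)) ~ 1e-15)
        M[0, 0] = 1.0
        M[-1, -1] = 1.0

        self.W = prior1[:, None] * M

        # fractional cell weights for Pr(p > p0): exact split of the
        # boundary cell keeps the indicator error at O(h^2)
        t0 = ndtri(self.p0)
        frac = np.empty(G)
        frac[0] = 0.0
        frac[1:-1] = np.clip((edges[1:] - t0) / h, 0.0, 1.0)
        frac[-1] = 1.0
        self.frac_exceed = frac
        self._Wf2 = self.W * frac[None, :]
        self._Wp2 = self.W * p_all[None, :]

        if self.delta1 is not None:
            d1 = self.delta1
            thr = p_all + d1           # p2 < p1 + delta1
            F = np.ones((G, G))
            fin = thr < 1.0
            t_i = np.full(G, np.inf)
            t_i[fin] = ndtri(thr[fin])
            Fi = np.clip((t_i[fin, None] - edges[None, :-1]) / h, 0.0, 1.0)
            rows = np.where(fin)[0]
            F[rows, 1:-1] = Fi
            F[rows, 0] = 1.0                       # p2 = 0 is always below
            F[rows, -1] = 0.0                      # p2 = 1 only if p1 > 1 - d1
            self._WF = self.W * F
        else:
            self._WF = None

    # -- tables -------------------------------------------------------------

    def table(self, n1: int, n2: int) -> dict[str, np.ndarray]:
        """Posterior summaries for every outcome (y1, y2) at sizes (n1, n2).

        Returns arrays of shape (n1+1, n2+1): ``pr1``, ``pr2`` (exceedance
        probabilities), ``mean1``, ``mean2`` and, when delta1 is set,
        ``pp_ni``.
        """
        key = (int(n1), int(n2))
        if key in self._tables:
            return self._tables[key]
        p = self.p_nodes
        L1 = binom.pmf(np.arange(n1 + 1)[:, None], n1, p[None, :])
        L2 = binom.pmf(np.arange(n2 + 1)[:, None], n2, p[None, :])
        B = self.W @ L2.T
        Z = L1 @ B
        out = {
            "pr1": ((L1 * self.frac_exceed) @ B) / Z,
            "pr2": (L1 @ (self._Wf2 @ L2.T)) / Z,
            "mean1": ((L1 * p) @ B) / Z,
            "mean2": (L1 @ (self._Wp2 @ L2.T)) / Z,
        }
        if self._WF is not None:
            out["pp_ni"] = (L1 @ (self._WF @ L2.T)) / Z
        self._tables[key] = out
        return out

    def joint_posterior(self, y1: int, n1: int, y2: int, n2: int) -> np.ndarray:
        """Normalized joint posterior mass over the (p1, p2) node grid.

        Entry (i, j) is the posterior probability of the cell with p1 at
        ``p_nodes[i]`` and p2 at ``p_nodes[j]``; used by the utility
        extension to combine efficacy and toxicity posteriors.
        """
        p = self.p_nodes
        L1 = binom.pmf(y1, n1, p)
        L2 = binom.pmf(y2, n2, p)
        post = self.W * np.outer(L1, L2)
        return post / post.sum()

    def summary(self, data: TrialData) -> PosteriorSummary:
        t = self.table(data.n1, data.n2)
        pp = t["pp_ni"][data.y1, data.y2] if "pp_ni" in t else None
        return PosteriorSummary(
            pr_exceed=(float(t["pr1"][data.y1, data.y2]),
                       float(t["pr2"][data.y1, data.y2])),
            pp_ni=None if pp is None else float(pp),
            post_mean=(float(t["mean1"][data.y1, data.y2]),
                       float(t["mean2"][data.y1, data.y2])),
            method="quadrature",
            tol=self.settings.tol,
        )


@lru_cache(maxsize=64)
def get_tables(hyper: DLMHyperparams, p0: float, delta1: float | None = None,
               settings: QuadratureSettings = QuadratureSettings()) -> DLMTables:
    """Memoized DLMTables factory (the usual entry point)."""
    return DLMTables(hyper, p0, delta1, settings)


def dlm_posterior(data: TrialData, hyper: DLMHyperparams, p0: float,
                  delta1: float | None = None,
                  settings: QuadratureSettings = QuadratureSettings(),
                  check: bool = True) -> PosteriorSummary:
    """Posterior summary for one observed outcome table.

    With ``check=True`` the integration is repeated at half the grid step
    and a :class:`NumericalError` is raised if any reported probability
    moves by more than ``settings.tol`` -- the integration never fails
    silently.
    """
    coarse = get_tables(hyper, p0, delta1, settings).summary(data)
    if not check:
        return coarse
    fine_settings = QuadratureSettings(
        mu_max=settings.mu_max, mu_step=settings.mu_step / 2.0,
        sigma_nodes=2 * settings.sigma_nodes, tol=settings.tol)
    fine = get_tables(hyper, p0, delta1, fine_settings).summary(data)
    devs = [abs(a - b) for a, b in zip(coarse.pr_exceed, fine.pr_exceed)]
    devs += [abs(a - b) for a, b in zip(coarse.post_mean, fine.post_mean)]
    if coarse.pp_ni is not None:
        devs.append(abs(coarse.pp_ni - fine.pp_ni))
    if max(devs) > settings.tol:
        raise NumericalError(
            f"quadrature not converged: max refinement change {max(devs):.2e} "
            f"exceeds tol {settings.tol:.1e}")
    return fine


# ---------------------------------------------------------------------------
# MCMC cross-check backend
# ---------------------------------------------------------------------------

def _log_target(mu1, mu2, lsig, y1, n1, y2, n2, hp: DLMHyperparams):
    sig = hp.xi + np.exp(lsig)
    lp = y1 * log_ndtr(mu1) + (n1 - y1) * log_ndtr(-mu1)
    lp += y2 * log_ndtr(mu2) + (n2 - y2) * log_ndtr(-mu2)
    lp += -0.5 * ((mu1 - hp.theta) / hp.sigma1) ** 2
    lp += -0.5 * ((mu2 - mu1) / sig) ** 2 - lsig
    # half-Cauchy density on sig > xi, plus log-Jacobian of sig = xi + e^lsig
    lp += -np.log1p(((sig - hp.xi) / hp.tau) ** 2) + lsig
    return lp


def dlm_posterior_mcmc(data: TrialData, hyper: DLMHyperparams, p0: float,
                       delta1: float | None = None, seed: int = 0,
                       chains: int = 256, warmup: int = 1500,
                       draws: int = 4000) -> tuple[PosteriorSummary, dict]:
    """Seeded random-walk Metropolis sampler for the same posterior.

    Runs ``chains`` independent chains vectorized across components and
    estimates Monte-Carlo standard errors from the spread of per-chain
    means.  Returns ``(summary, info)`` where ``info`` carries the SEs and
    acceptance rate.  Intended as an independent check on the quadrature.
    """
    rng = np.random.default_rng(seed)
    y1, n1, y2, n2 = data.y1, data.n1, data.y2, data.n2
    mu1 = np.full(chains, hyper.theta) + 0.5 * rng.standard_normal(chains)
    mu2 = mu1 + 0.5 * rng.standard_normal(chains)
    lsig = rng.standard_normal(chains) * 0.5
    lp = _log_target(mu1, mu2, lsig, y1, n1, y2, n2, hyper)
    scale = np.array([0.6, 0.6, 1.0])
    acc_hist = []
    keep_mu1 = np.empty((draws, chains))
    keep_mu2 = np.empty((draws, chains))
    for it in range(warmup + draws):
        prop = rng.standard_normal((3, chains)) * scale[:, None]
        m1p, m2p, lsp = mu1 + prop[0], mu2 + prop[1], lsig + prop[2]
        lpp = _log_target(m1p, m2p, lsp, y1, n1, y2, n2, hyper)
        acc = np.log(rng.random(chains)) < lpp - lp
        mu1 = np.where(acc, m1p, mu1)
        mu2 = np.where(acc, m2p, mu2)
        lsig = np.where(acc, lsp, lsig)
        lp = np.where(acc, lpp, lp)
        rate = acc.mean()
        if it < warmup:
            # Robbins-Monro drift toward ~28% joint acceptance
            scale *= np.exp(0.5 * (rate - 0.28) / np.sqrt(1 + it))
        else:
            keep_mu1[it - warmup] = mu1
            keep_mu2[it - warmup] = mu2
            acc_hist.append(rate)
    p1 = ndtr(keep_mu1)
    p2 = ndtr(keep_mu2)

    def _est(ind):
        chain_means = ind.mean(axis=0)
        return float(chain_means.mean()), float(chain_means.std(ddof=1) / np.sqrt(chains))

    pr1, se1 = _est(p1 > p0)
    pr2, se2 = _est(p2 > p0)
    m1_, sem1 = _est(p1)
    m2_, sem2 = _est(p2)
    info = {"se_pr_exceed": (se1, se2), "se_post_mean": (sem1, sem2),
            "accept_rate": float(np.mean(acc_hist))}
    pp = None
    if delta1 is not None:
        pp, sepp = _est(p2 - p1 < delta1)
        info["se_pp_ni"] = sepp
    return PosteriorSummary(pr_exceed=(pr1, pr2), pp_ni=pp,
                            post_mean=(m1_, m2_), method="mcmc"), info


# ---------------------------------------------------------------------------
# conjugate beta-binomial model (comparator designs)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BetaPosterior:
    a: float
    b: float
    pr_exceed: float
    post_mean: float


def bb_posterior(y: int, n: int, p0: float,
                 prior: tuple[float, float] | None = None) -> BetaPosterior:
    """Single-dose conjugate posterior under a Beta(p0, 1-p0) prior.

    ``prior`` overrides the default (p0, 1-p0) shape pair.  The exceedance
    probability Pr(p > p0 | y, n) is the regularized incomplete beta
    function evaluated in closed form.
    """
    if not (0 <= y <= n):
        raise ValueError("need 0 <= y <= n")
    a0, b0 = prior if prior is not None else (p0, 1.0 - p0)
    a, b = a0 + y, b0 + n - y
    return BetaPosterior(a=a, b=b,
                         pr_exceed=float(beta_dist.sf(p0, a, b)),
                         post_mean=a / (a + b))


_GL_U = leggauss(300)


def bb_pair_probs(y1, n1, y2, n2, p0: float, delta1: float = 0.0,
                  prior: tuple[float, float] | None = None) -> dict[str, float]:
    """Between-dose probabilities under independent beta-binomial posteriors.

    Returns Pr(p2 - p1 < delta1 | D) and Pr(p2 > p1 | D), integrating over
    the Beta posterior of p2 by its quantile transform (robust to the
    endpoint singularities of shape parameters below 1).
    """
    b1 = bb_posterior(y1, n1, p0, prior)
    b2 = bb_posterior(y2, n2, p0, prior)
    un, uw = _GL_U
    u = 0.5 * (un + 1.0)
    w = 0.5 * uw
    x2 = beta_dist.ppf(u, b2.a, b2.b)
    F1 = beta_dist.cdf(x2 - delta1, b1.a, b1.b)
    F1_0 = beta_dist.cdf(x2, b1.a, b1.b)
    return {
        "pp_ni": float(np.sum(w * (1.0 - F1))),
        "pr_greater": float(np.sum(w * F1_0)),
        "pr_exceed": (b1.pr_exceed, b2.pr_exceed),
        "post_mean": (b1.post_mean, b2.post_mean),
    }


class BBTables:
    """Posterior tables for independent beta-binomial dose models.

    Same table interface as :class:`DLMTables`, but the doses are modeled
    independently with conjugate Beta(p0, 1-p0) priors (the comparator
    designs' model).  ``delta1`` controls which between-dose probability
    populates ``pp_ni``; with ``delta1=0`` it is Pr(p2 - p1 < 0 | D) =
    1 - Pr(p2 > p1 | D), which lets a superiority rule with threshold c' be
    phrased as a two-outcome rule with c1 = c2 = 1 - c'.
    """

    def __init__(self, p0: float, delta1: float | None = None,
                 prior: tuple[float, float] | None = None):
        if not 0.0 < p0 < 1.0:
            raise ValueError("p0 must be in (0, 1)")
        self.p0 = float(p0)
        self.delta1 = None if delta1 is None else float(delta1)
        self.prior = prior if prior is not None else (p0, 1.0 - p0)
        self._tables: dict[tuple[int, int], dict[str, np.ndarray]] = {}

    def _marginal(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        a0, b0 = self.prior
        y = np.arange(n + 1)
        a = a0 + y
        b = b0 + n - y
        return a, b, beta_dist.sf(self.p0, a, b), a / (a + b)

    def table(self, n1: int, n2: int) -> dict[str, np.ndarray]:
        key = (int(n1), int(n2))
        if key in self._tables:
            return self._tables[key]
        a1, b1, pr1, m1 = self._marginal(n1)
        a2, b2, pr2, m2 = self._marginal(n2)
        shape = (n1 + 1, n2 + 1)
        out = {
            "pr1": np.broadcast_to(pr1[:, None], shape).copy(),
            "pr2": np.broadcast_to(pr2[None, :], shape).copy(),
            "mean1": np.broadcast_to(m1[:, None], shape).copy(),
            "mean2": np.broadcast_to(m2[None, :], shape).copy(),
        }
        if self.delta1 is not None:
            un, uw = _GL_U
            u = 0.5 * (un + 1.0)
            w = 0.5 * uw
            # Pr(p2 - p1 < d) = E_{p2}[1 - F1(p2 - d)] via the p2 quantile
            # transform; vectorized over the (y1, y2) grid
            x2 = beta_dist.ppf(u[None, :], a2[:, None], b2[:, None])  # (n2+1, U)
            x = x2[None, :, :] - self.delta1
            F1 = beta_dist.cdf(x, a1[:, None, None], b1[:, None, None])
            out["pp_ni"] = 1.0 - (F1 * w[None, None, :]).sum(axis=2)
        self._tables[key] = out
        return out


@lru_cache(maxsize=64)
def get_bb_tables(p0: float, delta1: float | None = None,
                  prior: tuple[float, float] | None = None) -> BBTables:
    """Memoized BBTables factory."""
    return BBTables(p0, delta1, prior)


# ---------------------------------------------------------------------------
# prior effective sample size
# ---------------------------------------------------------------------------

def _probit_normal_moments(theta: float, var: float) -> tuple[float, float]:
    """Exact mean and variance of Phi(mu) with mu ~ N(theta, var).

    E[Phi(mu)] = Phi(theta / sqrt(1+var)); the second moment is the bivariate
    normal orthant probability Phi2(h, h; rho) with rho = var/(1+var),
    evaluated through Owen's T function.
    """
    h = theta / np.sqrt(1.0 + var)
    rho = var / (1.0 + var)
    m = float(ndtr(h))
    a = np.sqrt((1.0 - rho) / (1.0 + rho))
    m2 = m - 2.0 * float(owens_t(h, a))
    return m, m2 - m * m


def prior_pess(hyper: DLMHyperparams, dose_index: int = 1,
               sigma_nodes: int = 200) -> float:
    """Prior effective sample size of the marginal prior of p_j.

    The prior marginal of p_j implied by the DLM is moment-matched to a
    Beta(a, b) with a + b = m(1-m)/v - 1 (prior mean m, variance v); the
    PESS is a + b, the implied count of phantom patients.  Values well
    below ~4 indicate a suitably vague prior.  Dose 2 mixes the extra
    half-Cauchy increment variance by quadrature.
    """
    if dose_index == 1:
        m, v = _probit_normal_moments(hyper.theta, hyper.sigma1 ** 2)
    elif dose_index == 2:
        un, uw = leggauss(sigma_nodes)
        u = 0.5 * (un + 1.0)
        w = 0.5 * uw
        sig = hyper.xi + hyper.tau * np.tan(0.5 * np.pi * u)
        m = 0.0
        m2 = 0.0
        for si, wi in zip(sig, w):
            mi, vi = _probit_normal_moments(hyper.theta, hyper.sigma1 ** 2 + si ** 2)
            m += wi * mi
            m2 += wi * (vi + mi * mi)
        v = m2 - m * m
    else:
        raise ValueError("dose_index must be 1 or 2")
    if v >= m * (1.0 - m):
        warnings.warn("degenerate prior variance; reporting PESS 0")
        return 0.0
    return round(m * (1.0 - m) / v - 1.0, 2)
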