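"""Joint toxicity-efficacy dose optimization via a risk-benefit utility.

The co-primary extension scores each dose with the utility

    u_j = p_j - rho * q_j

where p_j is the efficacy rate, q_j the toxicity rate and rho > 0 the
clinical exchange rate between the two (a unit of toxicity must be offset by
rho units of efficacy).  Toxicity is modeled by a second, independent
dynamic linear model of the same form as the efficacy model, anchored at the
toxicity upper limit q0 (theta_tox = probit(q0)); no efficacy-toxicity
association is modeled.

Per-dose monitoring becomes a joint admissibility check -- a dose is dropped
when it looks either futile or overly toxic,

    Pr(p_j > p0 | D_k) < a_k   or   Pr(q_j < q0 | D_k) < a_k

and the between-dose comparison runs the same triple-outcome rule on the
utility-scale noninferiority probability PP = Pr(u2 - u1 < delta1 | D_2),
with the margins delta1 < delta2 now read on the utility scale.

Because the joint outcome space (responders and toxicities per dose) is far
too large to enumerate, operating characteristics and the calibration of
this extension use seeded Monte Carlo; the posterior lookups themselves stay
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import binom

from .calibration import CalibrationTargets, InfeasibleDesignError
from .decisions import DesignParams
from .metrics import (OperatingCharacteristics, idr, mrid, sir, weighted_loss)
from .posterior import (DLMHyperparams, DLMTables, QuadratureSettings,
                        TrialData, get_tables, probit)
from .trial import Scenario

__all__ = [
    "UtilityParams",
    "utility",
    "round_half_up",
    "joint_monitor",
    "UtilityPosterior",
    "pp_utility_ni",
    "simulate_joint_oc",
    "calibrate_joint",
]


@dataclass(frozen=True)
class UtilityParams:
    """Toxicity-side parameters of the utility extension."""

    rho: float
    q0: float      # toxicity upper limit (a dose with q >= q0 is inadmissible)
    qA: float      # acceptable toxicity rate used in the calibration alternatives

    def __post_init__(self):
        if not self.rho > 0:
            raise ValueError("rho must be positive")
        if not 0.0 < self.qA < self.q0 < 1.0:
            raise ValueError("need 0 < qA < q0 < 1")


def utility(p: float, q: float, rho: float) -> float:
    """Risk-benefit utility u = p - rho*q."""
    if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    return p - rho * q


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, the convention used in printed result tables.

    The value is first snapped to 10 decimals so that binary float noise
    (e.g. 0.4665 arriving as 0.46649999999999997) cannot flip a tie.
    """
    d = Decimal(repr(x)).quantize(Decimal(1).scaleb(-10))
    return float(d.quantize(Decimal(1).scaleb(-ndigits),
                            rounding=ROUND_HALF_UP))


def joint_monitor(pr_safe: float, pr_effective: float, a_k: float) -> bool:
    """Joint admissibility: pass only if both posterior criteria clear a_k."""
    for v in (pr_safe, pr_effective, a_k):
        if not 0.0 <= v <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    return not (pr_safe < a_k or pr_effective < a_k)


def default_tox_hyper(q0: float) -> DLMHyperparams:
    """Toxicity DLM hyperparameters: same rule as efficacy, anchored at q0."""
    return DLMHyperparams(theta=probit(q0))


class UtilityPosterior:
    """Utility-scale posterior probabilities from two independent DLMs.

    Combines the efficacy posterior of (p1, p2) and the toxicity posterior
    of (q1, q2) into Pr(u2 - u1 < delta1 | D).  The two between-dose
    difference distributions are binned onto a fixed grid once per outcome,
    after which any pairing costs a single dot product -- cheap enough for
    Monte-Carlo operating characteristics.

    With rho = 0 the utility is the efficacy rate itself, and the efficacy
    model's PP_NI is returned exactly so the extension reduces to the
    efficacy-only design decision-for-decision.
    """

    def __init__(self, eff_tables: DLMTables, tox_tables: DLMTables,
                 rho: float, delta1: float, bins: int = 2000):
        self.eff = eff_tables
        self.tox = tox_tables
        self.rho = float(rho)
        self.delta1 = float(delta1)
        self.bins = bins
        self._edges = np.linspace(-1.0, 1.0, bins + 1)
        self._centers = 0.5 * (self._edges[:-1] + self._edges[1:])
        p = eff_tables.p_nodes
        diff = p[None, :] - p[:, None]            # p2 - p1 over the node grid
        self._idx_eff = np.clip(np.searchsorted(self._edges, diff.ravel(),
                                                side="right") - 1, 0, bins - 1)
        ptox = tox_tables.p_nodes
        difft = ptox[None, :] - ptox[:, None]
        self._idx_tox = np.clip(np.searchsorted(self._edges, difft.ravel(),
                                                side="right") - 1, 0, bins - 1)
        # F_A is evaluated at delta1 + rho * b for each toxicity-difference
        # bin center b; precompute the lookup indices once
        t = self.delta1 + self.rho * self._centers
        self._cdf_at = np.clip(np.searchsorted(self._edges[1:], t), 0, bins - 1)
        self._cdf_valid = t >= self._edges[0]
        self._eff_cdf_cache: dict[tuple, np.ndarray] = {}
        self._tox_hist_cache: dict[tuple, np.ndarray] = {}

    def _eff_cdf(self, y1, n1, y2, n2) -> np.ndarray:
        key = (y1, n1, y2, n2)
        if key not in self._eff_cdf_cache:
            w = self.eff.joint_posterior(y1, n1, y2, n2).ravel()
            hist = np.bincount(self._idx_eff, weights=w, minlength=self.bins)
            self._eff_cdf_cache[key] = np.cumsum(hist)
        return self._eff_cdf_cache[key]

    def _tox_hist(self, t1, n1, t2, n2) -> np.ndarray:
        key = (t1, n1, t2, n2)
        if key not in self._tox_hist_cache:
            w = self.tox.joint_posterior(t1, n1, t2, n2).ravel()
            self._tox_hist_cache[key] = np.bincount(
                self._idx_tox, weights=w, minlength=self.bins)
        return self._tox_hist_cache[key]

    def pp_ni(self, eff: TrialData, tox: TrialData) -> float:
        """Pr(u2 - u1 < delta1 | D) with independent p- and q-posteriors."""
        if self.rho == 0.0:
            tab = self.eff.table(eff.n1, eff.n2)
            return float(tab["pp_ni"][eff.y1, eff.y2])
        FA = self._eff_cdf(eff.y1, eff.n1, eff.y2, eff.n2)
        hB = self._tox_hist(tox.y1, tox.n1, tox.y2, tox.n2)
        vals = np.where(self._cdf_valid, FA[self._cdf_at], 0.0)
        return float(np.dot(hB, vals))


def pp_utility_ni(eff_data: TrialData, tox_data: TrialData,
                  hyper_eff: DLMHyperparams, hyper_tox: DLMHyperparams,
                  p0: float, q0: float, delta1: float, rho: float,
                  settings: QuadratureSettings = QuadratureSettings()) -> float:
    """One-shot utility-scale noninferiority probability Pr(u2 - u1 < delta1)."""
    eff_tab = get_tables(hyper_eff, p0, delta1, settings)
    tox_tab = get_tables(hyper_tox, q0, None, settings)
    return UtilityPosterior(eff_tab, tox_tab, rho, delta1).pp_ni(
        eff_data, tox_data)


# ---------------------------------------------------------------------------
# Monte-Carlo operating characteristics for the joint design
# ---------------------------------------------------------------------------

def _joint_tables(design: DesignParams, uparams: UtilityParams,
                  hyper_eff, hyper_tox, settings):
    if hyper_eff is None:
        hyper_eff = DLMHyperparams.default_for(design.p0)
    if hyper_tox is None:
        hyper_tox = default_tox_hyper(uparams.q0)
    eff = get_tables(hyper_eff, design.p0, design.delta1, settings)
    tox = get_tables(hyper_tox, uparams.q0, None, settings)
    return eff, tox


def simulate_joint_oc(scenario: Scenario, design: DesignParams,
                      uparams: UtilityParams,
                      hyper_eff: DLMHyperparams | None = None,
                      hyper_tox: DLMHyperparams | None = None,
                      reps: int = 10_000, seed: int = 0,
                      settings: QuadratureSettings = QuadratureSettings(),
                      ) -> OperatingCharacteristics:
    """Monte-Carlo operating characteristics of the co-primary design.

    The scenario must carry true toxicity rates (q1, q2); efficacy and
    toxicity outcomes are drawn independently within each arm.
    """
    if scenario.q1 is None or scenario.q2 is None:
        raise ValueError("joint simulation needs toxicity rates q1, q2")
    eff_tab, tox_tab = _joint_tables(design, uparams, hyper_eff, hyper_tox,
                                     settings)
    upost = UtilityPosterior(eff_tab, tox_tab, uparams.rho, design.delta1)
    n, m1, m2 = design.n, design.m1, design.m2
    rng = np.random.default_rng(seed)
    p1, p2, q1, q2 = scenario.p1, scenario.p2, scenario.q1, scenario.q2
    x1 = rng.binomial(m1, p1, reps)
    x2 = rng.binomial(m1, p2, reps)
    v1 = rng.binomial(m1, q1, reps)
    v2 = rng.binomial(m1, q2, reps)
    z1 = rng.binomial(m2, p1, reps)
    z2 = rng.binomial(m2, p2, reps)
    w1 = rng.binomial(m2, q1, reps)
    w2 = rng.binomial(m2, q2, reps)

    te = eff_tab.table(m1, m1)
    tt = tox_tab.table(m1, m1)
    ip1 = (te["pr1"][x1, x2] >= design.a1) & \
          ((1.0 - tt["pr1"][v1, v2]) >= design.a1)
    ip2 = (te["pr2"][x1, x2] >= design.a1) & \
          ((1.0 - tt["pr2"][v1, v2]) >= design.a1)

    y1 = np.where(ip1, x1 + z1, x1)
    y2 = np.where(ip2, x2 + z2, x2)
    u1 = np.where(ip1, v1 + w1, v1)
    u2 = np.where(ip2, v2 + w2, v2)

    fp1 = np.zeros(reps, dtype=bool)
    fp2 = np.zeros(reps, dtype=bool)
    est = np.empty((reps, 2))
    sizes = {(False, False): (m1, m1), (True, False): (n, m1),
             (False, True): (m1, n), (True, True): (n, n)}
    for (c1_, c2_), (n1_, n2_) in sizes.items():
        sel = (ip1 == c1_) & (ip2 == c2_)
        if not sel.any():
            continue
        te_ = eff_tab.table(n1_, n2_)
        tt_ = tox_tab.table(n1_, n2_)
        yy1, yy2, uu1, uu2 = y1[sel], y2[sel], u1[sel], u2[sel]
        if c1_:
            fp1[sel] = (te_["pr1"][yy1, yy2] >= design.a2) & \
                       ((1.0 - tt_["pr1"][uu1, uu2]) >= design.a2)
        if c2_:
            fp2[sel] = (te_["pr2"][yy1, yy2] >= design.a2) & \
                       ((1.0 - tt_["pr2"][uu1, uu2]) >= design.a2)
        est[sel, 0] = te_["mean1"][yy1, yy2]
        est[sel, 1] = te_["mean2"][yy1, yy2]

    dec = np.full(reps, "none", dtype=object)
    dec[fp1 & ~fp2] = "select_d1"
    dec[~fp1 & fp2] = "select_d2"
    both = np.where(fp1 & fp2)[0]
    if both.size:
        if design.c1 is None:
            raise ValueError("c1/c2 must be set to resolve both-pass outcomes")
        quad = np.stack([y1[both], y2[both], u1[both], u2[both]], axis=1)
        uniq, inv = np.unique(quad, axis=0, return_inverse=True)
        pps = np.array([
            upost.pp_ni(TrialData(int(a), n, int(b), n),
                        TrialData(int(c), n, int(d), n))
            for a, b, c, d in uniq])
        ppv = pps[inv]
        idx2 = both[ppv <= design.c1]
        idx1 = both[ppv > design.c2]
        idxi = both[(ppv > design.c1) & (ppv <= design.c2)]
        dec[idx2] = "select_d2"
        dec[idx1] = "select_d1"
        dec[idxi] = "inconclusive"

    freq = {k: float(np.mean(dec == k))
            for k in ("none", "select_d1", "select_d2", "inconclusive")}
    dev = est - np.array([p1, p2])[None, :]
    se = {k: float(np.sqrt(v * (1 - v) / reps)) for k, v in freq.items()}
    return OperatingCharacteristics(
        label=scenario.label or f"({p1:g},{p2:g};{q1:g},{q2:g})",
        p_none=freq["none"], p_d1=freq["select_d1"], p_d2=freq["select_d2"],
        p_inconclusive=freq["inconclusive"],
        go=(float(fp1.mean()), float(fp2.mean())),
        fwer_omp=float(np.mean(fp1 | fp2)),
        ass=(m1 + m2 * float(ip1.mean()), m1 + m2 * float(ip2.mean())),
        avg_bias=float(dev.mean(axis=0).mean()),
        avg_mse=float((dev ** 2).mean(axis=0).mean()),
        reps=reps, se=se)


# ---------------------------------------------------------------------------
# calibration of the joint design
# ---------------------------------------------------------------------------

def _joint_step1(targets: CalibrationTargets, p0, pA, q0, qA,
                 eff_tab, tox_tab, reps, rng):
    """Step-1 grid search with Monte-Carlo FWER/OMP/ASS estimates.

    For each (n, m1) the replication outcomes are drawn once; every
    (lambda, a2) grid point then reduces to vectorized thresholding of
    precomputed posterior lookups, exactly as in the efficacy-only search.
    """
    for n in range(targets.n_min, targets.n_max + 1):
        best = None
        for m1 in targets.m1_grid(n):
            m2 = n - m1
            draws = {}
            for tag, (pe, qt) in (("null", (p0, q0)), ("alt", (pA, qA))):
                x1 = rng.binomial(m1, pe, reps)
                x2 = rng.binomial(m1, pe, reps)
                v1 = rng.binomial(m1, qt, reps)
                v2 = rng.binomial(m1, qt, reps)
                z1 = rng.binomial(m2, pe, reps)
                z2 = rng.binomial(m2, pe, reps)
                w1 = rng.binomial(m2, qt, reps)
                w2 = rng.binomial(m2, qt, reps)
                te = eff_tab.table(m1, m1)
                tt = tox_tab.table(m1, m1)
                tenn, ttnn = eff_tab.table(n, n), tox_tab.table(n, n)
                tenm, ttnm = eff_tab.table(n, m1), tox_tab.table(n, m1)
                temn, ttmn = eff_tab.table(m1, n), tox_tab.table(m1, n)
                draws[tag] = {
                    "ie1": te["pr1"][x1, x2], "it1": 1.0 - tt["pr1"][v1, v2],
                    "ie2": te["pr2"][x1, x2], "it2": 1.0 - tt["pr2"][v1, v2],
                    "fe1_bb": tenn["pr1"][x1 + z1, x2 + z2],
                    "ft1_bb": 1.0 - ttnn["pr1"][v1 + w1, v2 + w2],
                    "fe2_bb": tenn["pr2"][x1 + z1, x2 + z2],
                    "ft2_bb": 1.0 - ttnn["pr2"][v1 + w1, v2 + w2],
                    "fe1_o": tenm["pr1"][x1 + z1, x2],
                    "ft1_o": 1.0 - ttnm["pr1"][v1 + w1, v2],
                    "fe2_o": temn["pr2"][x1, x2 + z2],
                    "ft2_o": 1.0 - ttmn["pr2"][v1, v2 + w2],
                }

            def _eval(tag, a1, a2):
                d = draws[tag]
                i1 = (d["ie1"] >= a1) & (d["it1"] >= a1)
                i2 = (d["ie2"] >= a1) & (d["it2"] >= a1)
                b = i1 & i2
                f1 = np.where(b, (d["fe1_bb"] >= a2) & (d["ft1_bb"] >= a2),
                              i1 & (d["fe1_o"] >= a2) & (d["ft1_o"] >= a2))
                f2 = np.where(b, (d["fe2_bb"] >= a2) & (d["ft2_bb"] >= a2),
                              i2 & (d["fe2_o"] >= a2) & (d["ft2_o"] >= a2))
                e = float(np.mean(f1 | f2))
                ass = m1 + m2 * 0.5 * (float(i1.mean()) + float(i2.mean()))
                return e, ass

            combos = []
            for a2 in targets.a2_grid:
                for lam in targets.lam_grid:
                    a1 = a2 * (m1 / n) ** lam
                    fwer, ass = _eval("null", a1, a2)
                    if fwer > targets.alpha1:
                        continue
                    omp, _ = _eval("alt", a1, a2)
                    combos.append((m1, lam, a2, a1, fwer, omp, ass))
            if not combos:
                continue
            max_omp = max(c[5] for c in combos)
            for m1_, lam, a2, a1, fwer, omp, ass in combos:
                if omp < max_omp - 0.01:
                    continue
                key = (ass, -omp, m1_, a2)
                if best is None or key < best[0]:
                    best = (key, (m1_, lam, a2, a1, fwer, omp, ass))
        if best is not None and best[1][5] >= targets.beta1:
            return n, best[1]
    raise InfeasibleDesignError(
        f"joint step 1: no n in [{targets.n_min}, {targets.n_max}] reaches "
        f"OMP >= {targets.beta1}")


def calibrate_joint(targets: CalibrationTargets, p0: float, pA: float,
                    q0: float, qA: float, rho: float,
                    delta1: float = 0.05, delta2: float = 0.2,
                    hyper_eff: DLMHyperparams | None = None,
                    hyper_tox: DLMHyperparams | None = None,
                    reps: int = 10_000, seed: int = 0,
                    settings: QuadratureSettings = QuadratureSettings(),
                    ) -> tuple[DesignParams, UtilityParams, dict]:
    """Two-step calibration of the joint toxicity-efficacy design.

    Step 1 uses the joint global null (p = p0, q = q0) and global
    alternative (p = pA, q = qA); step 2 runs the cutoff search under the
    utility-scale alternatives (pA, pA+delta1) and (pA, pA+delta2) with all
    toxicity rates at qA.  Operating characteristics are Monte-Carlo with
    ``reps`` replications per grid evaluation (the joint outcome space is
    too large to enumerate), so results carry simulation error; the seed
    makes them reproducible.
    """
    uparams = UtilityParams(rho=rho, q0=q0, qA=qA)
    if qA >= q0:
        raise InfeasibleDesignError("qA must be strictly below q0")
    if hyper_eff is None:
        hyper_eff = DLMHyperparams.default_for(p0)
    if hyper_tox is None:
        hyper_tox = default_tox_hyper(q0)
    eff_tab = get_tables(hyper_eff, p0, delta1, settings)
    tox_tab = get_tables(hyper_tox, q0, None, settings)
    rng = np.random.default_rng(seed)

    n, (m1, lam, a2, a1, fwer, omp, ass) = _joint_step1(
        targets, p0, pA, q0, qA, eff_tab, tox_tab, reps, rng)
    design = DesignParams.with_regularized_a1(
        n=n, m1=m1, a2=a2, lam=lam, p0=p0, pA=pA,
        delta1=delta1, delta2=delta2, wl=targets.wl)

    # step 2 under the utility-scale alternatives
    upost = UtilityPosterior(eff_tab, tox_tab, rho, delta1)
    masses = {}
    for role, p2 in (("star", pA + delta1), ("plus", pA + delta2)):
        sc = Scenario(pA, p2, qA, qA, label=role)
        fixed, ppv, ppw = _joint_comparison_mass(
            sc, design, eff_tab, tox_tab, upost, reps, rng)
        masses[role] = (fixed, ppv, ppw)

    best = None
    for c1 in targets.c_grid:
        for c2 in targets.c_grid:
            if c1 > c2:
                continue
            freqs = {}
            for role, (fixed, ppv, ppw) in masses.items():
                f = dict(fixed)
                f["select_d2"] += float(ppw[ppv <= c1].sum())
                f["select_d1"] += float(ppw[ppv > c2].sum())
                f["inconclusive"] += float(ppw[(ppv > c1) & (ppv <= c2)].sum())
                freqs[role] = f
            m = mrid(freqs["plus"])
            s = sir(freqs["star"], freqs["plus"])
            i = idr(freqs["star"], freqs["plus"])
            w = weighted_loss(i, s, targets.wl)
            if m <= targets.alpha2 and s <= targets.alpha3:
                key = (w, c2 - c1, c1)
                if best is None or key < best[0]:
                    best = (key, (c1, c2, m, s, i, w))
    if best is None:
        raise InfeasibleDesignError(
            "joint step 2: no (c1, c2) satisfies the MRID/SIR caps")
    c1, c2, m, s, i, w = best[1]
    info = {"fwer": fwer, "omp": omp, "ass_null": ass, "mrid": m, "sir": s,
            "idr": i, "wl": w, "reps": reps, "seed": seed}
    return design.with_cutoffs(float(c1), float(c2)), uparams, info


def _joint_comparison_mass(scenario, design, eff_tab, tox_tab, upost,
                           reps, rng):
    """Empirical decision mass as a function of the comparison cutoffs."""
    n, m1, m2 = design.n, design.m1, design.m2
    p1, p2, q1, q2 = scenario.p1, scenario.p2, scenario.q1, scenario.q2
    x1 = rng.binomial(m1, p1, reps)
    x2 = rng.binomial(m1, p2, reps)
    v1 = rng.binomial(m1, q1, reps)
    v2 = rng.binomial(m1, q2, reps)
    z1 = rng.binomial(m2, p1, reps)
    z2 = rng.binomial(m2, p2, reps)
    w1 = rng.binomial(m2, q1, reps)
    w2 = rng.binomial(m2, q2, reps)
    te = eff_tab.table(m1, m1)
    tt = tox_tab.table(m1, m1)
    ip1 = (te["pr1"][x1, x2] >= design.a1) & \
          ((1.0 - tt["pr1"][v1, v2]) >= design.a1)
    ip2 = (te["pr2"][x1, x2] >= design.a1) & \
          ((1.0 - tt["pr2"][v1, v2]) >= design.a1)
    y1 = np.where(ip1, x1 + z1, x1)
    y2 = np.where(ip2, x2 + z2, x2)
    u1 = np.where(ip1, v1 + w1, v1)
    u2 = np.where(ip2, v2 + w2, v2)

    fp1 = np.zeros(reps, dtype=bool)
    fp2 = np.zeros(reps, dtype=bool)
    sizes = {(False, False): (m1, m1), (True, False): (n, m1),
             (False, True): (m1, n), (True, True): (n, n)}
    for (c1_, c2_), (n1_, n2_) in sizes.items():
        sel = (ip1 == c1_) & (ip2 == c2_)
        if not sel.any():
            continue
        te_ = eff_tab.table(n1_, n2_)
        tt_ = tox_tab.table(n1_, n2_)
        yy1, yy2, uu1, uu2 = y1[sel], y2[sel], u1[sel], u2[sel]
        if c1_:
            fp1[sel] = (te_["pr1"][yy1, yy2] >= design.a2) & \
                       ((1.0 - tt_["pr1"][uu1, uu2]) >= design.a2)
        if c2_:
            fp2[sel] = (te_["pr2"][yy1, yy2] >= design.a2) & \
                       ((1.0 - tt_["pr2"][uu1, uu2]) >= design.a2)

    fixed = dict.fromkeys(("none", "select_d1", "select_d2", "inconclusive"), 0.0)
    fixed["none"] = float(np.mean(~fp1 & ~fp2))
    fixed["select_d1"] = float(np.mean(fp1 & ~fp2))
    fixed["select_d2"] = float(np.mean(~fp1 & fp2))
    both = np.where(fp1 & fp2)[0]
    if both.size == 0:
        return fixed, np.empty(0), np.empty(0)
    quad = np.stack([y1[both], y2[both], u1[both], u2[both]], axis=1)
    uniq, counts = np.unique(quad, axis=0, return_counts=True)
    pps = np.array([
        upost.pp_ni(TrialData(int(a), n, int(b), n),
                    TrialData(int(c), n, int(d), n))
        for a, b, c, d in uniq])
    return fixed, pps, counts / reps


def table2_utilities(scenarios: pd.DataFrame, rho: float) -> pd.DataFrame:
    """Per-dose utilities and the d2-d1 utility difference for a scenario set.

    Expects columns q1, p1, q2, p2; appends u1, u2 and du (= u2 - u1)
    rounded half-up to 2 decimals, the convention of printed result tables.
    """
    out = scenarios.copy()
    u1 = out["p1"] - rho * out["q1"]
    u2 = out["p2"] - rho * out["q2"]
    out["u1"] = [round_half_up(v) for v in u1]
    out["u2"] = [round_half_up(v) for v in u2]
    out["du"] = [round_half_up(v) for v in (u2 - u1)]
    return out
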