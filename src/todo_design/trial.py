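"""Two-stage trial simulation and exact operating characteristics.

`exact_oc` sums binomial probability mass over the complete outcome tree
(stage-1 counts, interim monitoring, conditional stage-2 counts, final
decision), giving Monte-Carlo-free operating characteristics for the
two-dose efficacy design.  `simulate_oc` is the replication-based twin used
for reporting with standard errors; `simulate_trial` runs a single seeded
trial and returns the full per-trial record.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import binom

from .decisions import DesignParams, TrialDecision, final_decision, monitor_dose
from .metrics import OperatingCharacteristics
from .posterior import (DLMHyperparams, DLMTables, QuadratureSettings,
                        TrialData, get_tables)

__all__ = ["Scenario", "TrialResult", "simulate_trial", "exact_oc",
           "simulate_oc"]


@dataclass(frozen=True)
class Scenario:
    """True per-dose rates defining a simulation scenario."""

    p1: float
    p2: float
    q1: float | None = None
    q2: float | None = None
    label: str = ""
    role: str = "other"   # global_null | global_alternative | HA_star | HA_plus | other

    def __post_init__(self):
        for r in (self.p1, self.p2, self.q1, self.q2):
            if r is not None and not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @classmethod
    def global_null(cls, p0: float) -> "Scenario":
        return cls(p0, p0, label="global null", role="global_null")

    @classmethod
    def global_alternative(cls, pA: float) -> "Scenario":
        return cls(pA, pA, label="global alternative", role="global_alternative")

    @classmethod
    def ha_star(cls, pA: float, delta1: float) -> "Scenario":
        return cls(pA, pA + delta1, label="HA*", role="HA_star")

    @classmethod
    def ha_plus(cls, pA: float, delta2: float) -> "Scenario":
        return cls(pA, pA + delta2, label="HA+", role="HA_plus")


@dataclass(frozen=True)
class TrialResult:
    """Record of a single simulated trial."""

    decision: TrialDecision
    enrollment: tuple[int, int]
    estimates: tuple[float, float]
    interim_pass: tuple[bool, bool]
    final_pass: tuple[bool, bool]
    data: TrialData


def _design_tables(design: DesignParams, hyper: DLMHyperparams | None,
                   settings: QuadratureSettings) -> DLMTables:
    if hyper is None:
        hyper = DLMHyperparams.default_for(design.p0)
    return get_tables(hyper, design.p0, design.delta1, settings)


def simulate_trial(scenario: Scenario, design: DesignParams,
                   hyper: DLMHyperparams | None = None, seed: int = 0,
                   settings: QuadratureSettings = QuadratureSettings(),
                   tables: DLMTables | None = None) -> TrialResult:
    """Simulate one two-stage trial; bitwise deterministic given ``seed``."""
    if tables is None:
        tables = _design_tables(design, hyper, settings)
    rng = np.random.default_rng(seed)
    n, m1, m2 = design.n, design.m1, design.m2
    x1 = int(rng.binomial(m1, scenario.p1))
    x2 = int(rng.binomial(m1, scenario.p2))
    t11 = tables.table(m1, m1)
    ip1 = monitor_dose(float(t11["pr1"][x1, x2]), design.a1)
    ip2 = monitor_dose(float(t11["pr2"][x1, x2]), design.a1)

    y1 = x1 + int(rng.binomial(m2, scenario.p1)) if ip1 else x1
    y2 = x2 + int(rng.binomial(m2, scenario.p2)) if ip2 else x2
    n1 = n if ip1 else m1
    n2 = n if ip2 else m1
    data = TrialData(y1=y1, n1=n1, y2=y2, n2=n2, stage=2)
    tab = tables.table(n1, n2)
    fp1 = ip1 and monitor_dose(float(tab["pr1"][y1, y2]), design.a2)
    fp2 = ip2 and monitor_dose(float(tab["pr2"][y1, y2]), design.a2)
    pp = float(tab["pp_ni"][y1, y2]) if (fp1 and fp2) else None
    dec = final_decision((fp1, fp2), pp, design)
    return TrialResult(decision=dec, enrollment=(n1, n2),
                       estimates=(float(tab["mean1"][y1, y2]),
                                  float(tab["mean2"][y1, y2])),
                       interim_pass=(ip1, ip2), final_pass=(fp1, fp2),
                       data=data)


@lru_cache(maxsize=256)
def _shift_pmf(m1: int, m2: int, p: float) -> np.ndarray:
    """A[x, y] = P(stage-2 count = y - x | x at stage 1), shape (m1+1, n+1)."""
    x = np.arange(m1 + 1)[:, None]
    y = np.arange(m1 + m2 + 1)[None, :]
    return binom.pmf(y - x, m2, p)


def exact_oc(scenario: Scenario, design: DesignParams,
             hyper: DLMHyperparams | None = None,
             settings: QuadratureSettings = QuadratureSettings(),
             tables: DLMTables | None = None,
             estimates: bool = True) -> OperatingCharacteristics:
    """Exact decision probabilities by full binomial enumeration.

    Every stage-1 cell (m1+1)^2 is propagated through interim monitoring and
    the conditional stage-2 outcome distributions; probabilities are summed,
    so results carry no Monte-Carlo error.  ``estimates=False`` skips the
    bias/MSE accumulation (used in tight calibration loops).
    """
    if tables is None:
        tables = _design_tables(design, hyper, settings)
    n, m1, m2 = design.n, design.m1, design.m2
    p1, p2 = scenario.p1, scenario.p2

    b1 = binom.pmf(np.arange(m1 + 1), m1, p1)
    b2 = binom.pmf(np.arange(m1 + 1), m1, p2)
    Pint = np.outer(b1, b2)
    t11 = tables.table(m1, m1)
    ipass1 = t11["pr1"] >= design.a1
    ipass2 = t11["pr2"] >= design.a1

    probs = dict.fromkeys(("none", "select_d1", "select_d2", "inconclusive"), 0.0)
    go = np.zeros(2)
    any_go = 0.0
    ebar = np.zeros(2)
    e2 = np.zeros(2)

    def _acc_est(mass, tab):
        nonlocal ebar, e2
        if not estimates:
            return
        for j, key in enumerate(("mean1", "mean2")):
            dev = tab[key] - (p1, p2)[j]
            ebar[j] += float((mass * tab[key]).sum())
            e2[j] += float((mass * dev ** 2).sum())

    # both dropped at interim
    mass_dd = Pint * (~ipass1 & ~ipass2)
    probs["none"] += float(mass_dd.sum())
    _acc_est(mass_dd, t11)

    A1 = _shift_pmf(m1, m2, p1)
    A2 = _shift_pmf(m1, m2, p2)

    # exactly one dose continues
    for which in (1, 2):
        mask = (ipass1 & ~ipass2) if which == 1 else (~ipass1 & ipass2)
        if not mask.any():
            continue
        if which == 1:
            G = A1.T @ (Pint * mask)          # (n+1, m1+1) over (y1, x2)
            tab = tables.table(n, m1)
            fin = tab["pr1"] >= design.a2
            sel = "select_d1"
        else:
            G = (Pint * mask) @ A2            # (m1+1, n+1) over (x1, y2)
            tab = tables.table(m1, n)
            fin = tab["pr2"] >= design.a2
            sel = "select_d2"
        psel = float((G * fin).sum())
        probs[sel] += psel
        probs["none"] += float((G * ~fin).sum())
        go[which - 1] += psel
        any_go += psel
        _acc_est(G, tab)

    # both continue
    mask11 = ipass1 & ipass2
    if mask11.any():
        G = A1.T @ (Pint * mask11) @ A2       # (n+1, n+1) over (y1, y2)
        tnn = tables.table(n, n)
        f1 = tnn["pr1"] >= design.a2
        f2 = tnn["pr2"] >= design.a2
        probs["none"] += float((G * (~f1 & ~f2)).sum())
        probs["select_d1"] += float((G * (f1 & ~f2)).sum())
        probs["select_d2"] += float((G * (~f1 & f2)).sum())
        go[0] += float((G * f1).sum())
        go[1] += float((G * f2).sum())
        any_go += float((G * (f1 | f2)).sum())
        both = f1 & f2
        if both.any():
            if design.c1 is None:
                raise ValueError("c1/c2 must be set to resolve both-pass outcomes")
            pp = tnn["pp_ni"]
            probs["select_d2"] += float((G * (both & (pp <= design.c1))).sum())
            probs["select_d1"] += float((G * (both & (pp > design.c2))).sum())
            probs["inconclusive"] += float(
                (G * (both & (pp > design.c1) & (pp <= design.c2))).sum())
        _acc_est(G, tnn)

    p_cont = np.array([float((Pint * ipass1).sum()), float((Pint * ipass2).sum())])
    ass = m1 + m2 * p_cont
    bias = float((ebar - (p1, p2)).mean()) if estimates else None
    mse = float(e2.mean()) if estimates else None
    return OperatingCharacteristics(
        label=scenario.label or f"({p1:g},{p2:g})",
        p_none=probs["none"], p_d1=probs["select_d1"],
        p_d2=probs["select_d2"], p_inconclusive=probs["inconclusive"],
        go=(float(go[0]), float(go[1])), fwer_omp=float(any_go),
        ass=(float(ass[0]), float(ass[1])), avg_bias=bias, avg_mse=mse,
        reps=None)


def simulate_oc(scenario: Scenario, design: DesignParams,
                hyper: DLMHyperparams | None = None, reps: int = 10_000,
                seed: int = 0,
                settings: QuadratureSettings = QuadratureSettings(),
                tables: DLMTables | None = None) -> OperatingCharacteristics:
    """Monte-Carlo operating characteristics over ``reps`` replications.

    Counts are drawn in a fixed order from a single seeded generator (stage
    1 dose 1, stage 1 dose 2, then the stage-2 increments), so results are
    reproducible bit-for-bit given (seed, reps).  Standard errors are the
    usual binomial ones.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if tables is None:
        tables = _design_tables(design, hyper, settings)
    n, m1, m2 = design.n, design.m1, design.m2
    p1, p2 = scenario.p1, scenario.p2
    rng = np.random.default_rng(seed)
    x1 = rng.binomial(m1, p1, reps)
    x2 = rng.binomial(m1, p2, reps)
    z1 = rng.binomial(m2, p1, reps)
    z2 = rng.binomial(m2, p2, reps)

    t11 = tables.table(m1, m1)
    ip1 = t11["pr1"][x1, x2] >= design.a1
    ip2 = t11["pr2"][x1, x2] >= design.a1
    y1 = np.where(ip1, x1 + z1, x1)
    y2 = np.where(ip2, x2 + z2, x2)

    fp1 = np.zeros(reps, dtype=bool)
    fp2 = np.zeros(reps, dtype=bool)
    ppv = np.full(reps, np.nan)
    est = np.empty((reps, 2))

    cases = {
        (False, False): (t11, m1, m1),
        (True, False): (tables.table(n, m1), n, m1),
        (False, True): (tables.table(m1, n), m1, n),
        (True, True): (tables.table(n, n), n, n),
    }
    for (c1_, c2_), (tab, _, _) in cases.items():
        sel = (ip1 == c1_) & (ip2 == c2_)
        if not sel.any():
            continue
        yy1, yy2 = y1[sel], y2[sel]
        if c1_:
            fp1[sel] = tab["pr1"][yy1, yy2] >= design.a2
        if c2_:
            fp2[sel] = tab["pr2"][yy1, yy2] >= design.a2
        if c1_ and c2_ and "pp_ni" in tab:
            ppv[sel] = tab["pp_ni"][yy1, yy2]
        est[sel, 0] = tab["mean1"][yy1, yy2]
        est[sel, 1] = tab["mean2"][yy1, yy2]

    dec = np.full(reps, "none", dtype=object)
    dec[fp1 & ~fp2] = "select_d1"
    dec[~fp1 & fp2] = "select_d2"
    both = fp1 & fp2
    if both.any():
        if design.c1 is None:
            raise ValueError("c1/c2 must be set to resolve both-pass outcomes")
        dec[both & (ppv <= design.c1)] = "select_d2"
        dec[both & (ppv > design.c2)] = "select_d1"
        dec[both & (ppv > design.c1) & (ppv <= design.c2)] = "inconclusive"

    freq = {k: float(np.mean(dec == k))
            for k in ("none", "select_d1", "select_d2", "inconclusive")}
    go = (float(fp1.mean()), float(fp2.mean()))
    ass = (m1 + m2 * float(ip1.mean()), m1 + m2 * float(ip2.mean()))
    dev = est - np.array([p1, p2])[None, :]
    se = {k: float(np.sqrt(v * (1 - v) / reps)) for k, v in freq.items()}
    se["fwer_omp"] = float(np.sqrt(np.mean(fp1 | fp2)
                                   * (1 - np.mean(fp1 | fp2)) / reps))
    return OperatingCharacteristics(
        label=scenario.label or f"({p1:g},{p2:g})",
        p_none=freq["none"], p_d1=freq["select_d1"], p_d2=freq["select_d2"],
        p_inconclusive=freq["inconclusive"], go=go,
        fwer_omp=float(np.mean(fp1 | fp2)), ass=ass,
        avg_bias=float(dev.mean(axis=0).mean()),
        avg_mse=float((dev ** 2).mean(axis=0).mean()),
        reps=reps, se=se)
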