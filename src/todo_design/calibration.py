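"""Two-step calibration of the design parameters, plus comparator designs.

Step 1 fixes the monitoring machinery (n, m1, a1, a2): over a grid of
(m1, lambda, a2) with the regularization a1 = a2 (m1/n)^lambda, it keeps the
combinations controlling the family-wise error rate under the global null at
alpha1, restricts to those whose overall monitoring power (OMP) under the
global alternative is within one percentage point of the best, picks the one
minimizing the global-null average sample size, and returns the smallest n
whose selected combination reaches the target OMP beta1.

Step 2 fixes the comparison cutoffs (c1, c2): over the cutoff grid it keeps
pairs controlling MRID at alpha2 and SIR at alpha3 under the two calibration
alternatives HA* = (pA, pA+delta1) and HA+ = (pA, pA+delta2), and picks the
pair minimizing the weighted loss WL = IDR + wl*SIR.

All operating characteristics here come from exact binomial enumeration, so
calibration is deterministic and reproducible run-to-run.

The module also calibrates the two comparator designs: the beta-binomial
variant of the same design (same algorithm, independent dose models) and the
DREAMM-2-style unoptimized design, and performs the exhaustive exact-binomial
search for Simon's optimal two-stage single-arm design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .decisions import DesignParams
from .metrics import idr as idr_fn
from .metrics import mrid as mrid_fn
from .metrics import sir as sir_fn
from .metrics import weighted_loss
from .posterior import (DLMHyperparams, QuadratureSettings, get_bb_tables,
                        get_tables)
from .trial import Scenario, exact_oc

__all__ = [
    "CalibrationTargets",
    "Step1Result",
    "Step2Result",
    "InfeasibleDesignError",
    "step1_search",
    "step2_search",
    "calibrate",
    "Dreamm2Design",
    "calibrate_dreamm2",
    "SimonDesign",
    "simon_two_stage",
]


class InfeasibleDesignError(RuntimeError):
    """No grid point satisfies the calibration constraints."""


def _default_a2_grid():
    return tuple(np.round(np.arange(0.50, 0.995, 0.01), 2))


def _default_lam_grid():
    return tuple(np.round(np.arange(0.1, 1.05, 0.1), 1))


def _default_c_grid():
    return tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


@dataclass(frozen=True)
class CalibrationTargets:
    """Error caps, power target and search grids for the calibration."""

    alpha1: float = 0.10      # FWER cap under the global null
    beta1: float = 0.95       # target OMP under the global alternative
    alpha2: float = 0.20      # MRID cap under HA+
    alpha3: float = 0.15      # SIR cap (averaged over HA*, HA+)
    wl: float = 0.40          # inconclusive discount in the weighted loss
    lam_grid: tuple = field(default_factory=_default_lam_grid)
    a2_grid: tuple = field(default_factory=_default_a2_grid)
    c_grid: tuple = field(default_factory=_default_c_grid)
    n_min: int = 10
    n_max: int = 60

    def __post_init__(self):
        for v in (self.alpha1, self.beta1, self.alpha2, self.alpha3, self.wl):
            if not 0.0 <= v <= 1.0:
                raise ValueError("caps and weights must lie in [0, 1]")
        if not (self.lam_grid and self.a2_grid and self.c_grid):
            raise ValueError("search grids must be non-empty")

    def m1_grid(self, n: int) -> range:
        """Stage-1 sizes searched for a given n: ceil(n/3) .. floor(2n/3)."""
        return range(max(1, math.ceil(n / 3)), min(n - 1, math.floor(2 * n / 3)) + 1)


@dataclass(frozen=True)
class Step1Result:
    design: DesignParams          # c1/c2 not yet set
    fwer: float
    omp: float
    ass_null: float
    trace: pd.DataFrame           # per-n selected optimum


@dataclass(frozen=True)
class Step2Result:
    design: DesignParams          # complete
    mrid: float
    sir: float
    idr: float
    wl_value: float
    trace: pd.DataFrame           # per (c1, c2) grid point


class _MonitorEngine:
    """FWER/OMP/ASS for one (n, m1, scenario) as fast functions of (a1, a2).

    The posterior exceedance tables do not depend on the cutoffs, so the
    whole (lambda, a2) grid reduces to boolean thresholding of precomputed
    arrays -- this is what makes the exhaustive step-1 search cheap.
    """

    def __init__(self, tables, n: int, m1: int, p1: float, p2: float):
        self.n, self.m1, self.m2 = n, m1, n - m1
        b1 = binom.pmf(np.arange(m1 + 1), m1, p1)
        b2 = binom.pmf(np.arange(m1 + 1), m1, p2)
        self.Pint = np.outer(b1, b2)
        t11 = tables.table(m1, m1)
        self.I1, self.I2 = t11["pr1"], t11["pr2"]
        x = np.arange(m1 + 1)[:, None]
        y = np.arange(n + 1)[None, :]
        self.A1 = binom.pmf(y - x, self.m2, p1)
        self.A2 = binom.pmf(y - x, self.m2, p2)
        self.F1nm = tables.table(n, m1)["pr1"]
        self.F2mn = tables.table(m1, n)["pr2"]
        tnn = tables.table(n, n)
        self.F1nn, self.F2nn = tnn["pr1"], tnn["pr2"]

    def eval(self, a1: float, a2: float) -> tuple[float, float]:
        """Return (P(at least one dose declared admissible), mean per-dose ASS)."""
        ip1 = self.I1 >= a1
        ip2 = self.I2 >= a1
        e = 0.0
        m10 = ip1 & ~ip2
        if m10.any():
            G = self.A1.T @ (self.Pint * m10)
            e += float((G * (self.F1nm >= a2)).sum())
        m01 = ~ip1 & ip2
        if m01.any():
            G = (self.Pint * m01) @ self.A2
            e += float((G * (self.F2mn >= a2)).sum())
        m11 = ip1 & ip2
        if m11.any():
            G = self.A1.T @ (self.Pint * m11) @ self.A2
            e += float((G * ((self.F1nn >= a2) | (self.F2nn >= a2))).sum())
        pc = 0.5 * (float((self.Pint * ip1).sum()) + float((self.Pint * ip2).sum()))
        return e, self.m1 + self.m2 * pc


def _get_backend_tables(backend: str, hyper, p0, delta1, settings):
    if backend == "dlm":
        if hyper is None:
            hyper = DLMHyperparams.default_for(p0)
        return get_tables(hyper, p0, delta1, settings)
    if backend == "bb":
        return get_bb_tables(p0, delta1)
    raise ValueError(f"unknown backend {backend!r}")


def step1_search(targets: CalibrationTargets, p0: float, pA: float,
                 hyper: DLMHyperparams | None = None,
                 delta1: float = 0.05, delta2: float = 0.2,
                 settings: QuadratureSettings = QuadratureSettings(),
                 backend: str = "dlm") -> Step1Result:
    """Step 1: choose (n, m1, a1, a2) by exact-enumeration grid search.

    Raises :class:`InfeasibleDesignError` (reporting the best OMP achieved)
    if no n in the search range reaches the target OMP.
    """
    tables = _get_backend_tables(backend, hyper, p0, None, settings)
    rows = []
    best_overall = None
    for n in range(targets.n_min, targets.n_max + 1):
        best = None    # (ass, -omp, m1, a2, lam, a1, fwer)
        for m1 in targets.m1_grid(n):
            null_eng = _MonitorEngine(tables, n, m1, p0, p0)
            alt_eng = _MonitorEngine(tables, n, m1, pA, pA)
            combos = []
            for a2 in targets.a2_grid:
                for lam in targets.lam_grid:
                    a1 = a2 * (m1 / n) ** lam
                    fwer, ass = null_eng.eval(a1, a2)
                    if fwer > targets.alpha1:
                        continue
                    omp, _ = alt_eng.eval(a1, a2)
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
        if best is None:
            continue
        m1_, lam, a2, a1, fwer, omp, ass = best[1]
        rows.append({"n": n, "m1": m1_, "lambda": lam, "a2": a2, "a1": a1,
                     "fwer": fwer, "omp": omp, "ass_null": ass})
        if best_overall is None or omp > best_overall["omp"]:
            best_overall = rows[-1]
        if omp >= targets.beta1:
            design = DesignParams.with_regularized_a1(
                n=n, m1=m1_, a2=a2, lam=lam, p0=p0, pA=pA,
                delta1=delta1, delta2=delta2, wl=targets.wl)
            return Step1Result(design=design, fwer=fwer, omp=omp,
                               ass_null=ass, trace=pd.DataFrame(rows))
    achieved = best_overall["omp"] if best_overall else float("nan")
    raise InfeasibleDesignError(
        f"no n in [{targets.n_min}, {targets.n_max}] reaches OMP >= "
        f"{targets.beta1}; best achieved OMP = {achieved:.4f}")


def _comparison_mass(design: DesignParams, tables, p1: float, p2: float):
    """Fixed decision probabilities plus the both-pass PP_NI mass spectrum.

    Returns (fixed, pp_values, pp_weights) where ``fixed`` contains the
    probability of each decision settled by monitoring alone, and the mass
    pairs describe the distribution of PP_NI over final outcomes where both
    doses passed -- all a (c1, c2) choice can still redistribute.
    """
    n, m1, m2 = design.n, design.m1, design.m2
    b1 = binom.pmf(np.arange(m1 + 1), m1, p1)
    b2 = binom.pmf(np.arange(m1 + 1), m1, p2)
    Pint = np.outer(b1, b2)
    t11 = tables.table(m1, m1)
    ip1 = t11["pr1"] >= design.a1
    ip2 = t11["pr2"] >= design.a1
    x = np.arange(m1 + 1)[:, None]
    y = np.arange(n + 1)[None, :]
    A1 = binom.pmf(y - x, m2, p1)
    A2 = binom.pmf(y - x, m2, p2)

    fixed = dict.fromkeys(("none", "select_d1", "select_d2", "inconclusive"), 0.0)
    fixed["none"] += float((Pint * (~ip1 & ~ip2)).sum())
    G10 = A1.T @ (Pint * (ip1 & ~ip2))
    f = tables.table(n, m1)["pr1"] >= design.a2
    fixed["select_d1"] += float((G10 * f).sum())
    fixed["none"] += float((G10 * ~f).sum())
    G01 = (Pint * (~ip1 & ip2)) @ A2
    f = tables.table(m1, n)["pr2"] >= design.a2
    fixed["select_d2"] += float((G01 * f).sum())
    fixed["none"] += float((G01 * ~f).sum())

    G = A1.T @ (Pint * (ip1 & ip2)) @ A2
    tnn = tables.table(n, n)
    f1 = tnn["pr1"] >= design.a2
    f2 = tnn["pr2"] >= design.a2
    fixed["none"] += float((G * (~f1 & ~f2)).sum())
    fixed["select_d1"] += float((G * (f1 & ~f2)).sum())
    fixed["select_d2"] += float((G * (~f1 & f2)).sum())
    both = f1 & f2
    return fixed, tnn["pp_ni"][both].ravel(), G[both].ravel()


def step2_search(design: DesignParams, targets: CalibrationTargets,
                 hyper: DLMHyperparams | None = None,
                 settings: QuadratureSettings = QuadratureSettings(),
                 backend: str = "dlm") -> Step2Result:
    """Step 2: choose (c1, c2) minimizing WL subject to MRID and SIR caps.

    Ties in WL are broken toward the smaller inconclusive zone (c2 - c1),
    then the smaller c1, making the search deterministic; with wl = 1 this
    collapses the zone entirely.
    """
    tables = _get_backend_tables(backend, hyper, design.p0, design.delta1,
                                 settings)
    masses = {}
    for role, p2 in (("star", design.pA + design.delta1),
                     ("plus", design.pA + design.delta2)):
        masses[role] = _comparison_mass(design, tables, design.pA, p2)

    rows = []
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
            m = mrid_fn(freqs["plus"])
            s = sir_fn(freqs["star"], freqs["plus"])
            i = idr_fn(freqs["star"], freqs["plus"])
            w = weighted_loss(i, s, targets.wl)
            feasible = (m <= targets.alpha2) and (s <= targets.alpha3)
            rows.append({"c1": c1, "c2": c2, "mrid": m, "sir": s, "idr": i,
                         "wl": w, "feasible": feasible})
            if feasible:
                key = (w, c2 - c1, c1)
                if best is None or key < best[0]:
                    best = (key, (c1, c2, m, s, i, w))
    trace = pd.DataFrame(rows)
    if best is None:
        raise InfeasibleDesignError(
            "no (c1, c2) satisfies the MRID/SIR caps; minimum achievable "
            f"MRID = {trace['mrid'].min():.4f}, SIR = {trace['sir'].min():.4f}")
    c1, c2, m, s, i, w = best[1]
    return Step2Result(design=design.with_cutoffs(float(c1), float(c2)),
                       mrid=m, sir=s, idr=i, wl_value=w, trace=trace)


def calibrate(p0: float, pA: float, delta1: float, delta2: float,
              targets: CalibrationTargets | None = None,
              hyper: DLMHyperparams | None = None,
              settings: QuadratureSettings = QuadratureSettings(),
              backend: str = "dlm") -> tuple[DesignParams, Step1Result, Step2Result]:
    """Run both calibration steps; returns (design, step1, step2)."""
    if targets is None:
        targets = CalibrationTargets()
    s1 = step1_search(targets, p0, pA, hyper, delta1, delta2, settings, backend)
    s2 = step2_search(s1.design, targets, hyper, settings, backend)
    return s2.design, s1, s2


# ---------------------------------------------------------------------------
# comparator designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dreamm2Design:
    """Unoptimized beta-binomial comparator with a superiority comparison.

    Both doses are monitored independently; if both pass, the higher dose is
    selected iff Pr(p2 > p1 | D2) >= c_prime, otherwise the lower dose (no
    inconclusive outcome).  Expressed on the PP_NI(0) scale this is a
    two-outcome rule with c1 = c2 = 1 - c_prime.
    """

    n: int
    m1: int
    interim_cutoff: float
    final_cutoff: float
    c_prime: float
    p0: float
    pA: float

    def as_design_params(self, delta1: float = 0.05, delta2: float = 0.2) -> DesignParams:
        c = 1.0 - self.c_prime
        return DesignParams(n=self.n, m1=self.m1, a1=self.interim_cutoff,
                            a2=self.final_cutoff, p0=self.p0, pA=self.pA,
                            delta1=delta1, delta2=delta2, c1=c, c2=c)

    def tables(self):
        """Comparison on Pr(p2 - p1 < 0 | D), i.e. the superiority scale."""
        return get_bb_tables(self.p0, 0.0)


def calibrate_dreamm2(n: int, m1: int, p0: float, pA: float,
                      early_stop_rate: float = 0.05,
                      alpha1: float = 0.10,
                      c_prime: float = 0.6) -> Dreamm2Design:
    """Calibrate the DREAMM-2-style comparator's two futility cutoffs.

    The interim cutoff is the largest posterior threshold whose per-dose
    early stopping probability under the promising rate pA stays at or
    below ``early_stop_rate``; the final cutoff is the smallest threshold
    whose family-wise error rate under the global null stays at or below
    ``alpha1``.  Candidate thresholds are the attainable posterior values,
    so both searches are exact.
    """
    tab = get_bb_tables(p0, 0.0)
    m2 = n - m1
    pr_int = tab.table(m1, m1)["pr1"][:, 0]          # Pr(p > p0 | y, m1)
    pmf_alt = binom.pmf(np.arange(m1 + 1), m1, pA)

    interim_cutoff = 0.0
    for cand in np.sort(np.unique(pr_int)):
        if pmf_alt[pr_int < cand].sum() <= early_stop_rate:
            interim_cutoff = float(cand)
        else:
            break

    pr_fin = tab.table(n, n)["pr1"][:, 0]            # Pr(p > p0 | y, n)
    pmf0_1 = binom.pmf(np.arange(m1 + 1), m1, p0)
    keep = pr_int >= interim_cutoff
    x = np.arange(m1 + 1)[:, None]
    y = np.arange(n + 1)[None, :]
    A = binom.pmf(y - x, m2, p0)
    dist_fin = (pmf0_1 * keep) @ A                   # P(pass interim, Y = y | p0)

    final_cutoff = None
    for cand in np.sort(np.unique(pr_fin)):
        g = dist_fin[pr_fin >= cand].sum()
        if 1.0 - (1.0 - g) ** 2 <= alpha1:
            final_cutoff = float(cand)
            break
    if final_cutoff is None:
        final_cutoff = 1.0
    return Dreamm2Design(n=n, m1=m1, interim_cutoff=interim_cutoff,
                         final_cutoff=final_cutoff, c_prime=c_prime,
                         p0=p0, pA=pA)


# ---------------------------------------------------------------------------
# Simon's optimal two-stage design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimonDesign:
    r1: int
    n1: int
    r: int
    n: int
    en_null: float        # expected sample size under H0
    type1: float
    power: float


def simon_two_stage(p0: float, pA: float, alpha: float, power: float,
                    n_max: int = 100) -> SimonDesign:
    """Exhaustive exact-binomial search for Simon's optimal two-stage design.

    Continue past stage 1 iff y1 > r1; declare the treatment active iff
    additionally the total responders exceed r.  Among all (r1, n1, r, n)
    with exact type I error <= alpha and exact power >= power, the design
    minimizing the expected sample size under H0 is returned.
    """
    if not 0.0 < p0 < pA < 1.0:
        raise ValueError("need 0 < p0 < pA < 1")
    best = None
    for n in range(2, n_max + 1):
        for n1 in range(1, n):
            n2 = n - n1
            y1 = np.arange(n1 + 1)
            b0 = binom.pmf(y1, n1, p0)
            bA = binom.pmf(y1, n1, pA)
            for r1 in range(0, n1):
                pet0 = binom.cdf(r1, n1, p0)
                en0 = n1 + (1.0 - pet0) * n2
                if best is not None and en0 >= best.en_null:
                    continue
                cont = y1[r1 + 1:]
                for r in range(r1, n):
                    a = float((b0[cont] * binom.sf(r - cont, n2, p0)).sum())
                    if a > alpha:
                        continue
                    pw = float((bA[cont] * binom.sf(r - cont, n2, pA)).sum())
                    if pw >= power:
                        best = SimonDesign(r1=r1, n1=n1, r=r, n=n,
                                           en_null=en0, type1=a, power=pw)
                    break   # larger r only loses power
    if best is None:
        raise InfeasibleDesignError(
            f"no two-stage design with n <= {n_max} meets alpha={alpha}, "
            f"power={power}")
    return best
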