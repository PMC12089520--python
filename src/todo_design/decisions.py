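"""Per-dose monitoring and triple-outcome decision rules.

A dose is dropped at analysis k when its posterior probability of beating
the historical control falls below the stage cutoff, Pr(p_j > p0 | D_k) < a_k
(strict).  When both doses survive to the final analysis, the between-dose
comparison is resolved three ways from PP_NI = Pr(p2 - p1 < delta1 | D_2):

    select d2      if PP_NI <= c1    (lower dose inferior)
    select d1      if PP_NI >  c2    (lower dose noninferior)
    inconclusive   if c1 < PP_NI <= c2

Boundary conventions follow the design's inequalities exactly.  Setting
c1 = c2 collapses the rule to a conventional two-outcome comparison.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .posterior import DLMHyperparams, DLMTables, QuadratureSettings, get_tables

__all__ = [
    "DesignParams",
    "TrialDecision",
    "monitor_dose",
    "optimal_dose",
    "triple_outcome",
    "final_decision",
    "decision_table",
    "plot_decision_tables",
]


class TrialDecision(str, enum.Enum):
    """Four-way terminal trial decision."""

    NONE = "none"
    SELECT_D1 = "select_d1"
    SELECT_D2 = "select_d2"
    INCONCLUSIVE = "inconclusive"

    def __str__(self):  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class DesignParams:
    """Full parameterization of the two-dose design decision machinery.

    The monitoring cutoffs obey the regularization a1 = a2 (m1/n)^lambda when
    built through :meth:`with_regularized_a1`.  ``c1``/``c2`` may be ``None``
    for a design whose between-dose comparison is not yet calibrated.
    """

    n: int
    m1: int
    a1: float
    a2: float
    p0: float
    pA: float
    delta1: float
    delta2: float
    c1: float | None = None
    c2: float | None = None
    lam: float | None = None
    wl: float = 0.4

    def __post_init__(self):
        if not 0 < self.m1 < self.n:
            raise ValueError("need 0 < m1 < n")
        if not (0.0 <= self.a1 <= 1.0 and 0.0 <= self.a2 <= 1.0):
            raise ValueError("monitoring cutoffs must lie in [0, 1]")
        if self.a1 > self.a2:
            raise ValueError("need a1 <= a2")
        if not 0.0 < self.delta1 < self.delta2:
            raise ValueError("need 0 < delta1 < delta2")
        if (self.c1 is None) != (self.c2 is None):
            raise ValueError("c1 and c2 must be set together")
        if self.c1 is not None and self.c1 > self.c2:
            raise ValueError("need c1 <= c2")
        if not 0.0 <= self.wl <= 1.0:
            raise ValueError("wl must lie in [0, 1]")

    @property
    def m2(self) -> int:
        return self.n - self.m1

    @classmethod
    def with_regularized_a1(cls, n, m1, a2, lam, **kw) -> "DesignParams":
        """Build with a1 = a2 (m1/n)^lambda, lambda in (0, 1]."""
        if not 0.0 < lam <= 1.0:
            raise ValueError("lambda must lie in (0, 1]")
        a1 = a2 * (m1 / n) ** lam
        return cls(n=n, m1=m1, a1=a1, a2=a2, lam=lam, **kw)

    def with_cutoffs(self, c1: float, c2: float) -> "DesignParams":
        return replace(self, c1=c1, c2=c2)


def optimal_dose(p1: float, p2: float, p0: float,
                 delta1: float, delta2: float,
                 q1: float | None = None, q2: float | None = None,
                 q0: float | None = None, rho: float = 0.0) -> TrialDecision:
    """Truth-level categorization of which dose (if any) is optimal.

    The lower dose is optimal when it beats the historical control and is
    noninferior to (or the only admissible alternative to) the higher dose;
    the higher dose when it beats the control and improves on the lower dose
    by at least the inferiority margin (or the lower dose is inadmissible);
    in between lies the truth-level inconclusive band.  With toxicity rates
    and q0 supplied, admissibility additionally requires q_j < q0 and the
    margins are read on the utility scale u_j = p_j - rho*q_j.
    """
    if q0 is not None:
        adm1 = p1 > p0 and q1 < q0
        adm2 = p2 > p0 and q2 < q0
        diff = (p2 - rho * q2) - (p1 - rho * q1)
    else:
        adm1 = p1 > p0
        adm2 = p2 > p0
        diff = p2 - p1
    eps = 1e-12    # guard against binary noise in rate differences
    if not adm1 and not adm2:
        return TrialDecision.NONE
    if adm1 and (diff <= delta1 + eps or not adm2):
        return TrialDecision.SELECT_D1
    if adm2 and (diff >= delta2 - eps or not adm1):
        return TrialDecision.SELECT_D2
    return TrialDecision.INCONCLUSIVE


def monitor_dose(pr_exceed: float, a_k: float) -> bool:
    """Per-dose monitoring: True = pass, False = drop (iff pr_exceed < a_k)."""
    if not (0.0 <= pr_exceed <= 1.0 and 0.0 <= a_k <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    return not (pr_exceed < a_k)


def triple_outcome(pp_ni: float, c1: float, c2: float) -> TrialDecision:
    """Three-way between-dose verdict from the noninferiority probability."""
    if c1 > c2:
        raise ValueError("need c1 <= c2")
    if pp_ni <= c1:
        return TrialDecision.SELECT_D2
    if pp_ni > c2:
        return TrialDecision.SELECT_D1
    return TrialDecision.INCONCLUSIVE


def final_decision(pass_flags: tuple[bool, bool], pp_ni: float | None,
                   design: DesignParams) -> TrialDecision:
    """Combine final monitoring flags with the between-dose comparison.

    A dose dropped earlier is never re-admitted; if exactly one dose passes
    the final monitoring it is selected outright, and only when both pass is
    the triple-outcome rule consulted.
    """
    pass1, pass2 = pass_flags
    if not pass1 and not pass2:
        return TrialDecision.NONE
    if pass1 != pass2:
        return TrialDecision.SELECT_D1 if pass1 else TrialDecision.SELECT_D2
    if design.c1 is None:
        raise ValueError("comparison cutoffs c1, c2 are not set")
    if pp_ni is None:
        raise ValueError("pp_ni required when both doses pass")
    return triple_outcome(pp_ni, design.c1, design.c2)


# ---------------------------------------------------------------------------
# exhaustive decision tables
# ---------------------------------------------------------------------------

def decision_table(design: DesignParams, hyper: DLMHyperparams | None = None,
                   settings: QuadratureSettings = QuadratureSettings(),
                   tables: DLMTables | None = None) -> dict[str, pd.DataFrame]:
    """Enumerate the decision for every possible outcome combination.

    Returns four long-format frames keyed ``interim`` (continue/drop per
    dose over stage-1 counts), ``final_both`` (four-way decision over final
    totals when both doses survived the interim), and ``final_d1_only`` /
    ``final_d2_only`` (the surviving dose's totals against the dropped
    dose's frozen stage-1 count).  These are the go/no-go charts a trial
    team would pre-generate before enrollment.
    """
    if hyper is None:
        hyper = DLMHyperparams.default_for(design.p0)
    if tables is None:
        tables = get_tables(hyper, design.p0, design.delta1, settings)
    n, m1 = design.n, design.m1

    t11 = tables.table(m1, m1)
    g1, g2 = np.meshgrid(np.arange(m1 + 1), np.arange(m1 + 1), indexing="ij")
    interim = pd.DataFrame({
        "y1": g1.ravel(), "y2": g2.ravel(),
        "continue_d1": (t11["pr1"] >= design.a1).ravel(),
        "continue_d2": (t11["pr2"] >= design.a1).ravel(),
    })

    tnn = tables.table(n, n)
    f1 = tnn["pr1"] >= design.a2
    f2 = tnn["pr2"] >= design.a2
    dec = np.full(f1.shape, TrialDecision.NONE.value, dtype=object)
    dec[f1 & ~f2] = TrialDecision.SELECT_D1.value
    dec[~f1 & f2] = TrialDecision.SELECT_D2.value
    if design.c1 is not None:
        pp = tnn["pp_ni"]
        both = f1 & f2
        dec[both & (pp <= design.c1)] = TrialDecision.SELECT_D2.value
        dec[both & (pp > design.c2)] = TrialDecision.SELECT_D1.value
        dec[both & (pp > design.c1) & (pp <= design.c2)] = \
            TrialDecision.INCONCLUSIVE.value
    elif np.any(f1 & f2):
        raise ValueError("c1/c2 must be set to label both-pass cells")
    g1, g2 = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    final_both = pd.DataFrame({"y1": g1.ravel(), "y2": g2.ravel(),
                               "decision": dec.ravel()})

    out = {"interim": interim, "final_both": final_both}
    for which in (1, 2):
        t = tables.table(n, m1) if which == 1 else tables.table(m1, n)
        pr = t["pr1"] if which == 1 else t["pr2"]
        sel = (TrialDecision.SELECT_D1 if which == 1
               else TrialDecision.SELECT_D2).value
        lab = np.where(pr >= design.a2, sel, TrialDecision.NONE.value)
        a1_, a2_ = np.meshgrid(np.arange(pr.shape[0]), np.arange(pr.shape[1]),
                               indexing="ij")
        out[f"final_d{which}_only"] = pd.DataFrame(
            {"y1": a1_.ravel(), "y2": a2_.ravel(), "decision": lab.ravel()})
    return out


_DECISION_COLORS = {
    "none": "#bdbdbd",
    "select_d1": "#1b9e77",
    "select_d2": "#7570b3",
    "inconclusive": "#fdb863",
}


def plot_decision_tables(tables: dict[str, pd.DataFrame], path: str | None = None):
    """Render the interim and final decision charts as colored grids."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch

    keys = [k for k in ("interim", "final_both", "final_d1_only",
                        "final_d2_only") if k in tables]
    fig, axes = plt.subplots(1, len(keys), figsize=(4.2 * len(keys), 4.2))
    axes = np.atleast_1d(axes)
    for ax, key in zip(axes, keys):
        df = tables[key]
        ny1 = df["y1"].max() + 1
        ny2 = df["y2"].max() + 1
        img = np.zeros((ny1, ny2, 3))
        if key == "interim":
            lab = np.where(df["continue_d1"] & df["continue_d2"], "both",
                           np.where(df["continue_d1"], "d1 only",
                                    np.where(df["continue_d2"], "d2 only",
                                             "stop")))
            colors = {"both": "#1b9e77", "d1 only": "#66c2a5",
                      "d2 only": "#8da0cb", "stop": "#bdbdbd"}
        else:
            lab = df["decision"].to_numpy()
            colors = _DECISION_COLORS
        for (y1, y2, lv) in zip(df["y1"], df["y2"], lab):
            img[y1, y2] = matplotlib.colors.to_rgb(colors[lv])
        ax.imshow(img.transpose(1, 0, 2), origin="lower")
        ax.set_xlabel("responders at $d_1$")
        ax.set_ylabel("responders at $d_2$")
        ax.set_title(key.replace("_", " "))
        ax.legend(handles=[Patch(color=c, label=l) for l, c in colors.items()],
                  fontsize=7, loc="upper left")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
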