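"""Design operating-characteristic summaries.

Vocabulary (all probabilities, reported in percent at presentation):

FWER / OMP : probability of declaring at least one dose admissible at the
             final monitoring -- a family-wise type I error under the global
             null (both doses futile) and the overall monitoring power under
             the global alternative (both promising).
Go%        : per-dose probability of passing both monitoring stages.
SIR        : size of the inconclusive region, averaged across the two
             calibration alternatives HA* and HA+.
IDR        : incorrect decision rate, 0.5 P(d2 or none | HA*) +
             0.5 P(d1 or none | HA+); inconclusive outcomes are excluded.
MRID       : P(select d1 | HA+), the rate of picking the inadequate dose.
WL         : IDR + wl * SIR, the step-2 calibration objective.
ASS        : average per-dose sample size over replications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OperatingCharacteristics",
    "idr",
    "sir",
    "mrid",
    "weighted_loss",
    "power_bound",
    "bias_mse",
]

_DECISIONS = ("none", "select_d1", "select_d2", "inconclusive")


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Operating characteristics of one design under one scenario."""

    label: str
    p_none: float
    p_d1: float
    p_d2: float
    p_inconclusive: float
    go: tuple[float, float]
    fwer_omp: float
    ass: tuple[float, float]
    avg_bias: float | None = None
    avg_mse: float | None = None
    reps: int | None = None            # None = exact enumeration
    se: dict | None = None

    @property
    def frequencies(self) -> dict[str, float]:
        return {"none": self.p_none, "select_d1": self.p_d1,
                "select_d2": self.p_d2, "inconclusive": self.p_inconclusive}

    def row(self) -> dict:
        """Result-table row, rates in percent to match the usual reporting."""
        return {
            "scenario": self.label,
            "sel_d1_pct": 100 * self.p_d1,
            "sel_d2_pct": 100 * self.p_d2,
            "sir_pct": 100 * self.p_inconclusive,
            "none_pct": 100 * self.p_none,
            "ass_d1": self.ass[0],
            "ass_d2": self.ass[1],
            "go_d1_pct": 100 * self.go[0],
            "go_d2_pct": 100 * self.go[1],
            "fwer_omp_pct": 100 * self.fwer_omp,
            "avg_bias": self.avg_bias,
            "avg_mse": self.avg_mse,
        }


def _check_freq(freq: dict) -> dict:
    missing = [k for k in _DECISIONS if k not in freq]
    if missing:
        raise ValueError(f"decision frequencies missing keys {missing}")
    total = sum(freq[k] for k in _DECISIONS)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"decision frequencies sum to {total}, not 1")
    return freq


def idr(freq_ha_star: dict, freq_ha_plus: dict,
        weights: tuple[float, float] = (0.5, 0.5)) -> float:
    """Incorrect decision rate across the two calibration alternatives.

    Under HA* (lower dose noninferior) the errors are selecting d2 or no
    dose; under HA+ (lower dose inferior) they are selecting d1 or no dose.
    Inconclusive outcomes are not errors here -- they are priced separately
    through the SIR.  ``weights`` generalizes the default equal weighting.
    """
    fs = _check_freq(freq_ha_star)
    fp = _check_freq(freq_ha_plus)
    w1, w2 = weights
    return (w1 * (fs["select_d2"] + fs["none"])
            + w2 * (fp["select_d1"] + fp["none"]))


def sir(freq_ha_star: dict, freq_ha_plus: dict) -> float:
    """Size of the inconclusive region, averaged across HA* and HA+."""
    return 0.5 * (_check_freq(freq_ha_star)["inconclusive"]
                  + _check_freq(freq_ha_plus)["inconclusive"])


def mrid(freq_ha_plus: dict) -> float:
    """Rate of selecting the inadequate lower dose under HA+."""
    return _check_freq(freq_ha_plus)["select_d1"]


def weighted_loss(idr_value: float, sir_value: float, wl: float) -> float:
    """WL = IDR + wl * SIR; wl in [0,1] discounts inconclusiveness."""
    if not 0.0 <= wl <= 1.0:
        raise ValueError("wl must lie in [0, 1]")
    return idr_value + wl * sir_value


def power_bound(omp: float) -> float:
    """Per-dose monitoring power implied by an OMP for two i.i.d. doses.

    If the two doses' admissibility declarations were independent with
    common power g, then OMP = 1 - (1-g)^2, i.e. g = 1 - sqrt(1 - OMP).
    Information borrowing makes the realized per-dose power exceed this
    bound, which is how a target OMP translates into a per-dose guarantee.
    """
    if not 0.0 <= omp <= 1.0:
        raise ValueError("omp must lie in [0, 1]")
    return 1.0 - np.sqrt(1.0 - omp)


def bias_mse(estimates: np.ndarray, truths) -> tuple[float, float]:
    """Dose-averaged bias and MSE of replication-wise rate estimates.

    ``estimates`` has shape (reps, 2) of posterior means at trial end;
    ``truths`` the true per-dose rates.  Bias and squared error are averaged
    over replications within dose, then across the two doses.
    """
    est = np.asarray(estimates, dtype=float)
    tr = np.asarray(truths, dtype=float)
    if est.ndim != 2 or est.shape[1] != tr.shape[0]:
        raise ValueError("estimates must be (reps, n_doses)")
    dev = est - tr[None, :]
    return float(dev.mean(axis=0).mean()), float((dev ** 2).mean(axis=0).mean())
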