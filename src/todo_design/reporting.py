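"""Run configuration, scenario fixtures, result tables and manifests.

The operational shell around the statistical core: a validated run
configuration, the built-in simulation scenario sets, functions that turn a
calibrated design plus a scenario set into the standard result table (one
row per scenario x design), and the wl sensitivity sweep.  Every report is
accompanied by a manifest (config hash, seed, package version) from which it
can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .calibration import (CalibrationTargets, calibrate, calibrate_dreamm2,
                          step2_search)
from .decisions import DesignParams, optimal_dose
from .metrics import weighted_loss
from .posterior import DLMHyperparams, QuadratureSettings, probit
from .trial import Scenario, exact_oc, simulate_oc

__all__ = [
    "RunConfig",
    "builtin_scenarios",
    "run_scenarios",
    "wl_sweep",
    "manifest",
]


# ---------------------------------------------------------------------------
# configuration schema
# ---------------------------------------------------------------------------

class DesignBlock(BaseModel):
    p0: float = Field(gt=0, lt=1)
    pA: float = Field(gt=0, lt=1)
    delta1: float = Field(gt=0)
    delta2: float = Field(gt=0)
    alpha1: float = Field(default=0.10, ge=0, le=1)
    beta1: float = Field(default=0.95, ge=0, le=1)
    alpha2: float = Field(default=0.20, ge=0, le=1)
    alpha3: float = Field(default=0.15, ge=0, le=1)
    wl: float = Field(default=0.40, ge=0, le=1)
    theta: float | None = None          # defaults to probit(p0)
    sigma1: float = Field(default=3.0, gt=0)
    xi: float = 0.0
    tau: float = Field(default=1.0, gt=0)
    n_min: int = Field(default=10, ge=2)
    n_max: int = Field(default=60, ge=2)
    # toxicity extension (all three required together)
    q0: float | None = Field(default=None, gt=0, lt=1)
    qA: float | None = Field(default=None, gt=0, lt=1)
    rho: float | None = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check(self):
        if self.delta1 >= self.delta2:
            raise ValueError("need delta1 < delta2")
        if self.p0 >= self.pA:
            raise ValueError("need p0 < pA")
        tox = (self.q0, self.qA, self.rho)
        if any(v is not None for v in tox) and any(v is None for v in tox):
            raise ValueError("q0, qA and rho must be supplied together")
        if self.q0 is not None and not self.qA < self.q0:
            raise ValueError("need qA < q0")
        return self

    def hyper(self) -> DLMHyperparams:
        theta = probit(self.p0) if self.theta is None else self.theta
        return DLMHyperparams(theta=theta, sigma1=self.sigma1,
                              xi=self.xi, tau=self.tau)

    def targets(self) -> CalibrationTargets:
        return CalibrationTargets(alpha1=self.alpha1, beta1=self.beta1,
                                  alpha2=self.alpha2, alpha3=self.alpha3,
                                  wl=self.wl, n_min=self.n_min,
                                  n_max=self.n_max)


class ExecutionBlock(BaseModel):
    backend: str = Field(default="exact", pattern="^(exact|mc)$")
    reps: int = Field(default=10_000, ge=1)
    seed: int = Field(default=0, ge=0)
    workers: int = Field(default=1, ge=1)


class OutputBlock(BaseModel):
    directory: str = "results"
    formats: list[str] = ["csv", "json"]


class RunConfig(BaseModel):
    """Validated run configuration (design, execution and output blocks)."""

    design: DesignBlock
    execution: ExecutionBlock = ExecutionBlock()
    output: OutputBlock = OutputBlock()

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.model_validate(data)

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True)


def manifest(config: RunConfig, extra: dict | None = None) -> dict:
    """Reproducibility manifest: config hash, seed and software version."""
    out = {
        "config_sha256": hashlib.sha256(
            config.canonical_json().encode()).hexdigest(),
        "seed": config.execution.seed,
        "version": __version__,
        "config": config.model_dump(),
    }
    if extra:
        out.update(extra)
    return out


# ---------------------------------------------------------------------------
# scenario fixtures
# ---------------------------------------------------------------------------

_TABLE1 = [
    ("1.1", 0.20, 0.20), ("1.2", 0.40, 0.40), ("1.3", 0.40, 0.45),
    ("1.4", 0.40, 0.60), ("1.5", 0.20, 0.40), ("1.6", 0.40, 0.70),
    ("1.7", 0.40, 0.43), ("1.8", 0.45, 0.40), ("1.9", 0.60, 0.40),
]

# (label, q1, p1, q2, p2) -- co-primary toxicity/efficacy scenario set
_TABLE2 = [
    ("2.1", 0.40, 0.20, 0.40, 0.20),
    ("2.2", 0.25, 0.40, 0.25, 0.40),
    ("2.3", 0.25, 0.40, 0.25, 0.60),
    ("2.4", 0.25, 0.40, 0.25, 0.45),
    ("2.5", 0.30, 0.20, 0.35, 0.20),
    ("2.6", 0.40, 0.25, 0.50, 0.30),
    ("2.7", 0.15, 0.20, 0.20, 0.40),
    ("2.8", 0.15, 0.40, 0.20, 0.65),
    ("2.9", 0.15, 0.50, 0.20, 0.75),
    ("2.10", 0.20, 0.40, 0.40, 0.60),
    ("2.11", 0.15, 0.40, 0.20, 0.45),
    ("2.12", 0.05, 0.40, 0.20, 0.50),
    ("2.13", 0.05, 0.50, 0.20, 0.60),
    ("2.14", 0.20, 0.50, 0.45, 0.40),
    ("2.15", 0.15, 0.50, 0.20, 0.45),
]


def builtin_scenarios(name: str) -> list[Scenario]:
    """Built-in scenario sets: ``table1`` (efficacy) and ``table2`` (joint)."""
    if name == "table1":
        return [Scenario(p1, p2, label=lab) for lab, p1, p2 in _TABLE1]
    if name == "table2":
        return [Scenario(p1, p2, q1=q1, q2=q2, label=lab)
                for lab, q1, p1, q2, p2 in _TABLE2]
    raise ValueError(f"unknown scenario set {name!r}")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _scenario_idr_wl(oc, scenario: Scenario, design: DesignParams) -> dict:
    """Per-scenario IDR/WL against the truth-level optimal dose."""
    opt = optimal_dose(scenario.p1, scenario.p2, design.p0,
                       design.delta1, design.delta2)
    freq = oc.frequencies
    correct = freq.get(opt.value, 0.0) if opt.value != "inconclusive" else None
    wrong = sum(v for k, v in freq.items()
                if k not in (opt.value, "inconclusive"))
    return {
        "optimal": opt.value,
        "correct_pct": None if correct is None else 100 * correct,
        "idr_pct": 100 * wrong,
        "wl_pct": 100 * weighted_loss(wrong, freq["inconclusive"], design.wl),
    }


def run_scenarios(config: RunConfig,
                  scenario_set: list[Scenario] | str = "table1",
                  methods: tuple[str, ...] = ("todo",),
                  designs: dict[str, DesignParams] | None = None,
                  ) -> tuple[pd.DataFrame, dict]:
    """Operating-characteristic report over a scenario set.

    ``methods`` may include ``todo`` (the DLM-based design), ``todo-bb``
    (the same decision machinery on independent beta-binomial models) and
    ``dreamm2`` (the unoptimized comparator).  Designs are calibrated on
    the fly unless supplied in ``designs``; the comparators reuse the TODO
    design's (n, m1) as in the published comparison.  Returns the report
    frame and its manifest.
    """
    if isinstance(scenario_set, str):
        scenario_set = builtin_scenarios(scenario_set)
    db = config.design
    ex = config.execution
    designs = dict(designs or {})
    backends: dict[str, tuple[DesignParams, object]] = {}

    if any(m in methods for m in ("todo", "todo-bb", "dreamm2")):
        if "todo" in designs:
            todo = designs["todo"]
        else:
            todo, _, _ = calibrate(db.p0, db.pA, db.delta1, db.delta2,
                                   db.targets(), db.hyper())
        if "todo" in methods:
            backends["todo"] = (todo, None)
        if "todo-bb" in methods:
            if "todo-bb" in designs:
                bb = designs["todo-bb"]
            else:
                tb = db.targets()
                bb_targets = CalibrationTargets(
                    alpha1=tb.alpha1, beta1=tb.beta1, alpha2=tb.alpha2,
                    alpha3=tb.alpha3, wl=tb.wl, n_min=todo.n, n_max=todo.n)
                bb, _, _ = calibrate(db.p0, db.pA, db.delta1, db.delta2,
                                     bb_targets, backend="bb")
            from .posterior import get_bb_tables
            backends["todo-bb"] = (bb, get_bb_tables(db.p0, db.delta1))
        if "dreamm2" in methods:
            d2 = calibrate_dreamm2(todo.n, todo.m1, db.p0, db.pA,
                                   alpha1=db.alpha1)
            backends["dreamm2"] = (
                d2.as_design_params(db.delta1, db.delta2), d2.tables())

    rows = []
    for method, (design, tables) in backends.items():
        for i, sc in enumerate(scenario_set):
            if ex.backend == "exact":
                oc = exact_oc(sc, design, db.hyper(), tables=tables)
            else:
                oc = simulate_oc(sc, design, db.hyper(), reps=ex.reps,
                                 seed=ex.seed + i, tables=tables)
            row = {"method": method, **oc.row(),
                   **_scenario_idr_wl(oc, sc, design)}
            rows.append(row)
    report = pd.DataFrame(rows)
    extra = {"designs": {k: asdict(v[0]) for k, v in backends.items()}}
    return report, manifest(config, extra)


def wl_sweep(config: RunConfig, wl_grid=None,
             design: DesignParams | None = None,
             scenario_set: list[Scenario] | str = "table1",
             ) -> tuple[pd.DataFrame, dict]:
    """Re-run the cutoff calibration for each wl and report the effect.

    For every wl on the grid the step-2 search is repeated with the step-1
    design fixed; the returned frame carries the calibrated (c1, c2) and,
    per scenario, the correct-selection percentage and weighted loss -- the
    data behind the wl-sensitivity figure.
    """
    if wl_grid is None:
        wl_grid = np.round(np.arange(0.0, 1.01, 0.1), 2)
    if isinstance(scenario_set, str):
        scenario_set = builtin_scenarios(scenario_set)
    db = config.design
    if design is None:
        from .calibration import step1_search
        design = step1_search(db.targets(), db.p0, db.pA, db.hyper(),
                              db.delta1, db.delta2).design
    rows = []
    tb = db.targets()
    for wl in wl_grid:
        t = CalibrationTargets(alpha1=tb.alpha1, beta1=tb.beta1,
                               alpha2=tb.alpha2, alpha3=tb.alpha3,
                               wl=float(wl), n_min=tb.n_min, n_max=tb.n_max)
        s2 = step2_search(design, t, db.hyper())
        from dataclasses import replace
        d = replace(s2.design, wl=float(wl))
        for sc in scenario_set:
            oc = exact_oc(sc, d, db.hyper())
            info = _scenario_idr_wl(
                oc, sc, d) if sc.label else {}
            rows.append({"wl": float(wl), "c1": d.c1, "c2": d.c2,
                         "scenario": sc.label,
                         "sel_d1_pct": 100 * oc.p_d1,
                         "sel_d2_pct": 100 * oc.p_d2,
                         "sir_pct": 100 * oc.p_inconclusive, **info})
    return pd.DataFrame(rows), manifest(config)
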