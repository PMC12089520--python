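"""Monitoring rule, triple-outcome comparison and exhaustive decision tables."""

import numpy as np
import pytest

from todo_design import (DesignParams, TrialDecision, decision_table,
                         final_decision, monitor_dose, optimal_dose,
                         triple_outcome)

from conftest import DELTA1, DELTA2, P0, PA


def test_monitor_dose_boundaries():
    assert monitor_dose(0.0, 0.1) is False          # clearly futile: drop
    assert monitor_dose(0.1, 0.1) is True           # strict inequality: pass
    assert monitor_dose(1.0, 0.99) is True
    with pytest.raises(ValueError):
        monitor_dose(1.2, 0.5)


def test_triple_outcome_rule():
    assert triple_outcome(0.9, 0.3, 0.8) is TrialDecision.SELECT_D1
    assert triple_outcome(0.3, 0.3, 0.8) is TrialDecision.SELECT_D2   # PP <= c1
    assert triple_outcome(0.5, 0.3, 0.8) is TrialDecision.INCONCLUSIVE
    with pytest.raises(ValueError):
        triple_outcome(0.5, 0.8, 0.3)


def test_triple_outcome_degenerates_to_two_outcomes():
    assert triple_outcome(0.5, 0.5, 0.5) is TrialDecision.SELECT_D2
    assert triple_outcome(0.500001, 0.5, 0.5) is TrialDecision.SELECT_D1
    # no PP value can land in an empty inconclusive zone
    for pp in np.linspace(0, 1, 101):
        assert triple_outcome(pp, 0.5, 0.5) is not TrialDecision.INCONCLUSIVE


def test_final_decision_routes(example_design):
    d = example_design
    assert final_decision((False, False), None, d) is TrialDecision.NONE
    # a single survivor is selected outright, whatever the comparison says
    assert final_decision((True, False), 0.01, d) is TrialDecision.SELECT_D1
    assert final_decision((False, True), 0.99, d) is TrialDecision.SELECT_D2
    mid = 0.5 * (d.c1 + d.c2)
    assert final_decision((True, True), mid, d) is TrialDecision.INCONCLUSIVE


def test_design_params_invariants():
    with pytest.raises(ValueError):
        DesignParams(n=10, m1=10, a1=0.1, a2=0.5, p0=P0, pA=PA,
                     delta1=DELTA1, delta2=DELTA2)
    with pytest.raises(ValueError):
        DesignParams(n=10, m1=5, a1=0.6, a2=0.5, p0=P0, pA=PA,
                     delta1=DELTA1, delta2=DELTA2)
    with pytest.raises(ValueError):
        DesignParams(n=10, m1=5, a1=0.1, a2=0.5, p0=P0, pA=PA,
                     delta1=0.2, delta2=0.1)
    d = DesignParams.with_regularized_a1(n=29, m1=10, a2=0.9, lam=0.5,
                                         p0=P0, pA=PA, delta1=DELTA1,
                                         delta2=DELTA2)
    assert d.a1 == pytest.approx(0.9 * (10 / 29) ** 0.5)
    assert d.a1 <= d.a2
    assert d.m2 == 19


@pytest.mark.parametrize("p1, p2, expected", [
    (0.20, 0.20, TrialDecision.NONE),              # both at the control rate
    (0.40, 0.40, TrialDecision.SELECT_D1),         # noninferior lower dose
    (0.40, 0.60, TrialDecision.SELECT_D2),         # substantially better d2
    (0.20, 0.40, TrialDecision.SELECT_D2),         # d1 futile
    (0.60, 0.40, TrialDecision.SELECT_D1),         # decreasing efficacy
    (0.40, 0.50, TrialDecision.INCONCLUSIVE),      # gap inside (delta1, delta2)
])
def test_optimal_dose_truth_categorization(p1, p2, expected):
    assert optimal_dose(p1, p2, P0, DELTA1, DELTA2) is expected


def test_optimal_dose_joint_with_toxicity():
    # equally effective, but the higher dose is overly toxic
    assert optimal_dose(0.5, 0.5, 0.25, DELTA1, DELTA2,
                        q1=0.2, q2=0.45, q0=0.4, rho=0.67) \
        is TrialDecision.SELECT_D1


@pytest.fixture(scope="module")
def tabs(example_design, hyper):
    return decision_table(example_design, hyper)


class TestDecisionTables:

    def test_partition(self, tabs, example_design):
        n = example_design.n
        counts = tabs["final_both"]["decision"].value_counts()
        assert counts.sum() == (n + 1) ** 2
        assert set(counts.index) <= {"none", "select_d1", "select_d2",
                                     "inconclusive"}

    def test_interim_monotone(self, tabs, example_design):
        m1 = example_design.m1
        cont = tabs["interim"].pivot(index="y1", columns="y2",
                                     values="continue_d1").to_numpy()
        assert np.all(cont[1:] >= cont[:-1])   # more responders never hurts

    def test_interim_origin_drops_both(self, tabs):
        row = tabs["interim"].query("y1 == 0 and y2 == 0").iloc[0]
        assert not row["continue_d1"] and not row["continue_d2"]

    def test_equal_cutoffs_remove_inconclusive(self, example_design, hyper):
        from dataclasses import replace
        d = replace(example_design, c1=0.55, c2=0.55)
        tabs = decision_table(d, hyper)
        assert (tabs["final_both"]["decision"] != "inconclusive").all()

    def test_raising_c2_shrinks_select_d1(self, example_design, hyper):
        from dataclasses import replace
        lo = decision_table(example_design, hyper)["final_both"]
        hi = decision_table(replace(example_design, c2=0.9),
                            hyper)["final_both"]
        assert (hi["decision"] == "select_d1").sum() <= \
            (lo["decision"] == "select_d1").sum()
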