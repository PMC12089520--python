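"""Two-step design calibration and the comparator design searches."""

import numpy as np
import pytest
from scipy.stats import binom

from todo_design import (CalibrationTargets, InfeasibleDesignError, Scenario,
                         TrialDecision, calibrate_dreamm2, exact_oc,
                         get_bb_tables, simon_two_stage, step1_search,
                         step2_search, triple_outcome)

from conftest import DELTA1, DELTA2, P0, PA


class TestStep1:

    def test_degenerate_no_monitoring(self):
        """a2 = 0 never drops a dose, so OMP is 1 at the smallest n."""
        t = CalibrationTargets(alpha1=1.0, beta1=0.9, a2_grid=(0.0,),
                               lam_grid=(1.0,), n_min=6, n_max=8)
        res = step1_search(t, P0, PA)
        assert res.design.n == 6
        assert res.omp == pytest.approx(1.0)
        assert res.ass_null == pytest.approx(6.0)

    def test_reference_configuration(self, ref_targets, ref_design):
        d = ref_design
        assert d.a1 <= d.a2
        assert 0 < d.m1 < d.n
        # the chosen design controls FWER and reaches the OMP target
        null = exact_oc(Scenario(P0, P0), d, estimates=False)
        alt = exact_oc(Scenario(PA, PA), d, estimates=False)
        assert null.fwer_omp <= ref_targets.alpha1 + 1e-12
        assert alt.fwer_omp >= ref_targets.beta1 - 1e-12

    def test_reproducible(self, ref_targets, hyper, ref_design):
        again = step1_search(ref_targets, P0, PA, hyper).design
        assert (again.n, again.m1, again.a1, again.a2) == \
            (ref_design.n, ref_design.m1, ref_design.a1, ref_design.a2)

    def test_relaxed_alpha1_never_needs_more_patients(self, hyper):
        t_tight = CalibrationTargets(alpha1=0.10, beta1=0.90, n_min=15,
                                     n_max=35)
        t_loose = CalibrationTargets(alpha1=0.20, beta1=0.90, n_min=15,
                                     n_max=35)
        n_tight = step1_search(t_tight, P0, PA, hyper).design.n
        n_loose = step1_search(t_loose, P0, PA, hyper).design.n
        assert n_loose <= n_tight

    def test_infeasible_reports_best_omp(self, hyper):
        t = CalibrationTargets(beta1=0.999, n_min=10, n_max=14)
        with pytest.raises(InfeasibleDesignError, match="best achieved OMP"):
            step1_search(t, P0, PA, hyper)


class TestStep2:

    def test_constraints_hold_by_construction(self, ref_targets, ref_design):
        s2 = step2_search(ref_design, ref_targets)
        assert s2.mrid <= ref_targets.alpha2 + 1e-12
        assert s2.sir <= ref_targets.alpha3 + 1e-12
        assert s2.design.c1 <= s2.design.c2

    def test_full_discount_closes_inconclusive_zone(self, ref_targets,
                                                    ref_design):
        t = CalibrationTargets(alpha1=ref_targets.alpha1,
                               beta1=ref_targets.beta1,
                               alpha2=ref_targets.alpha2,
                               alpha3=ref_targets.alpha3, wl=1.0,
                               n_min=ref_targets.n_min,
                               n_max=ref_targets.n_max)
        s2 = step2_search(ref_design, t)
        assert s2.design.c1 == s2.design.c2

    def test_zero_sir_cap_forces_two_outcome_rule(self, ref_targets,
                                                  ref_design):
        t = CalibrationTargets(alpha3=0.0, wl=0.4,
                               n_min=ref_targets.n_min,
                               n_max=ref_targets.n_max)
        s2 = step2_search(ref_design, t)
        assert s2.sir == pytest.approx(0.0, abs=1e-12)
        assert s2.design.c1 == s2.design.c2


@pytest.fixture(scope="module")
def d2():
    return calibrate_dreamm2(n=29, m1=10, p0=P0, pA=PA)


class TestDreamm2:

    def test_early_stop_rate_controlled(self, d2):
        """Interim early stopping under pA stays at or below 5%, recomputed
        by direct enumeration of the conjugate posterior."""
        tab = get_bb_tables(P0, 0.0).table(d2.m1, d2.m1)
        pr = tab["pr1"][:, 0]
        rate = binom.pmf(np.arange(d2.m1 + 1), d2.m1, PA)[
            pr < d2.interim_cutoff].sum()
        assert rate <= 0.05 + 1e-12
        assert d2.interim_cutoff > 0.0    # the zero cutoff is only the anchor

    def test_fwer_controlled(self, d2):
        oc = exact_oc(Scenario(P0, P0), d2.as_design_params(DELTA1, DELTA2),
                      tables=d2.tables(), estimates=False)
        assert oc.fwer_omp <= 0.10 + 1e-12

    def test_boundary_selects_higher_dose(self, d2):
        """Pr(p2 > p1) exactly at c' maps to selecting d2 (>= convention)."""
        pp_at_boundary = 1.0 - d2.c_prime
        dec = triple_outcome(pp_at_boundary, 1 - d2.c_prime, 1 - d2.c_prime)
        assert dec is TrialDecision.SELECT_D2


class TestSimon:

    def test_reference_design(self):
        d = simon_two_stage(0.2, 0.4, alpha=0.0519, power=0.87)
        assert (d.r1, d.n1, d.r, d.n) == (5, 21, 13, 46)

    def test_exact_error_rates_oracle(self):
        """Recompute type I error and power by direct binomial summation."""
        d = simon_two_stage(0.2, 0.4, alpha=0.0519, power=0.87)
        for p, target, bound in ((0.2, d.type1, 0.0519),
                                 (0.4, d.power, None)):
            y1 = np.arange(d.r1 + 1, d.n1 + 1)
            prob = (binom.pmf(y1, d.n1, p)
                    * binom.sf(d.r - y1, d.n - d.n1, p)).sum()
            assert prob == pytest.approx(target, abs=1e-12)
        assert d.type1 <= 0.0519 and d.power >= 0.87

    def test_unconstrained_is_minimal(self):
        d = simon_two_stage(0.2, 0.4, alpha=1.0, power=0.0, n_max=10)
        assert d.n == 2 and d.n1 == 1

    def test_infeasible_raises(self):
        with pytest.raises(InfeasibleDesignError):
            simon_two_stage(0.2, 0.25, alpha=0.01, power=0.99, n_max=30)
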