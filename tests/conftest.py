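import pytest

from todo_design import (CalibrationTargets, DesignParams, DLMHyperparams,
                         calibrate, get_tables)

P0, PA = 0.2, 0.4
DELTA1, DELTA2 = 0.05, 0.2


@pytest.fixture(scope="session")
def hyper():
    return DLMHyperparams.default_for(P0)


@pytest.fixture(scope="session")
def tables(hyper):
    return get_tables(hyper, P0, DELTA1)


@pytest.fixture(scope="session")
def ref_targets():
    return CalibrationTargets(n_min=20, n_max=40)


@pytest.fixture(scope="session")
def ref_design(ref_targets, hyper):
    """The fully calibrated reference design (both calibration steps)."""
    design, _, _ = calibrate(P0, PA, DELTA1, DELTA2, ref_targets, hyper)
    return design


@pytest.fixture(scope="session")
def example_design():
    """A fixed, plausible design for rule-level tests (no calibration run)."""
    return DesignParams(n=28, m1=14, a1=0.64, a2=0.91, p0=P0, pA=PA,
                        delta1=DELTA1, delta2=DELTA2, c1=0.5, c2=0.6, wl=0.4)
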