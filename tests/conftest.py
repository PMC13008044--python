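import math

import pytest

from qmsp import (
    AlleleEfficiencyProfile,
    AssayConfig,
    AssaySpec,
    RunConfig,
    SimulationConfig,
)


def brute_force_ct(n_m: float, n_u: float, e_m: float, e_u: float, q: float) -> float:
    """Independent oracle for the two-pool threshold cycle.

    Accumulates copies cycle by integer cycle and places the crossing by
    log-linear interpolation within the crossing cycle.
    """
    total = n_m + n_u
    assert 0 < total < q
    prev = total
    cycle = 0
    while True:
        cycle += 1
        n_m *= 1.0 + e_m
        n_u *= 1.0 + e_u
        total = n_m + n_u
        if total >= q:
            frac = (math.log(q) - math.log(prev)) / (math.log(total) - math.log(prev))
            return (cycle - 1) + frac
        prev = total
        assert cycle < 10_000


@pytest.fixture
def unbiased_pair():
    """MSP target + unbiased MIP reference for LINE-1, efficiency 0.90."""
    msp = AssaySpec("L1-Me", "MSP", "LINE1", AlleleEfficiencyProfile(0.90, 0.90))
    mip = AssaySpec("L1-Ref", "MIP", "LINE1", AlleleEfficiencyProfile(0.90, 0.90))
    return msp, mip


@pytest.fixture
def biased_mip():
    """MIP reference that amplifies originally-methylated templates better."""
    return AssaySpec("L1-Ref1", "MIP", "LINE1", AlleleEfficiencyProfile(0.95, 0.80))


@pytest.fixture
def noise_free():
    return SimulationConfig(seed=0, ct_noise_sd=0.0)


def run_config(assays, formula="PFAFFL", element="LINE1", **kw):
    """RunConfig for a single MSP/MIP pair with declared efficiencies."""
    return RunConfig(
        assays=[
            AssayConfig(a.assay_id, a.role, a.element, efficiency=a.profile.e_meth)
            for a in assays
        ],
        formula={element: formula},
        **kw,
    )
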