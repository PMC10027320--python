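"""Shared fixtures: reference motif models and frozen fixed-point values."""
import numpy as np
import pytest

from cosubflux import (EnzymeParams, PoolSpec, build_single_reaction_model)


@pytest.fixture
def ref_enzymes():
    """Reference kinetics: Etot=0.01 mM, kcat=100 /s, KM=0.05 -> Vmax=1 mM/s;
    background turnover enzyme at 1.2x Vmax."""
    e0 = EnzymeParams(kcat=100.0, Etot=0.01, KM_f=0.05)
    ea = EnzymeParams(kcat=100.0, Etot=0.012, KM_f=0.05)
    return e0, ea


@pytest.fixture
def ref_single_model(ref_enzymes):
    """Single-reaction motif at the worked-example operating point
    (Atot = 1 mM, kin = 0.5 mM/s, kout = 0.1 /s)."""
    e0, ea = ref_enzymes
    return build_single_reaction_model(enzyme_primary=e0, enzyme_background=ea,
                                       pool=PoolSpec("A", 1.0),
                                       kin=0.5, kout=0.1)


@pytest.fixture
def worked_fixed_point():
    """Closed-form fixed point at the reference operating point.

    alpha = 1.2 - 0.5 = 0.7
    m0* = 0.7*0.5*0.05 / ((1-0.5)*(1.2*1 - 0.5*1.05)) = 0.0175/0.3375
    m1* = 0.5/0.1, a1* = 0.5*0.05/0.7, a0* = 1 - a1*
    """
    m0 = 0.0175 / 0.3375
    a1 = 0.025 / 0.7
    return {"alpha": 0.7, "m0": m0, "m1": 5.0, "a0": 1.0 - a1, "a1": a1,
            "state": np.array([m0, 5.0, 1.0 - a1, a1])}
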