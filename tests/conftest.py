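import numpy as np
import pytest

from co2exchange import (
    FitOptions,
    PhysioParams,
    RespiratoryConstants,
    VentilationRecord,
    theta_from_physio,
)
from co2exchange.cohort import ProtocolSpec, SubjectSpec, generate_subject


@pytest.fixture(scope="session")
def constants():
    return RespiratoryConstants()


@pytest.fixture(scope="session")
def median_physio():
    """Cohort-median physiology with a 20-s total transport delay."""
    return PhysioParams(VL=2.28, VB=4.67, Q=1.20, VCO2=0.12, tau1=10.0, tau2=10.0)


@pytest.fixture(scope="session")
def median_theta(median_physio):
    return theta_from_physio(median_physio, ts_s=5.0)


@pytest.fixture(scope="session")
def flat_record():
    """A constant-ventilation record at the steady state of the median
    physiology (x1 = lam*VCO2/u)."""
    n = 60
    x1 = 863.0 * 0.12 / 2.24
    return VentilationRecord(
        ts_s=5.0,
        t_s=np.arange(n) * 5.0,
        petco2=np.full(n, x1),
        vdot=np.full(n, 2.24),
        subject_id="flat",
    )


@pytest.fixture(scope="session")
def discrete_subject(median_physio):
    """A noiseless subject generated by the identification recursion itself
    (the self-consistent parameter-recovery oracle)."""
    spec = SubjectSpec(
        physio=median_physio,
        protocol=ProtocolSpec(seed=3),
        noise_sd=0.0,
        seed=7,
        subject_id="oracle",
    )
    return generate_subject(spec, method="discrete")


@pytest.fixture(scope="session")
def fast_fit_options():
    """Fewer starts than the default for unit-test speed; determinism and
    convergence on clean oracles are unaffected."""
    return FitOptions(n_starts=3, seed=1)
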