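import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import polyadd as pa

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: the reference simulation conditions (1 M monomer units at 85 C,
#: unbonding 1e-6 1/s, bonding 7.4e-5 L/(mol s))
REF_KPLUS = 7.4e-5
REF_KMINUS = 1e-6
REF_U = 1.0
REF_T = 358.15


@pytest.fixture(scope="session")
def ref_rates() -> pa.RateConstants:
    return pa.RateConstants(kplus=REF_KPLUS, kminus=REF_KMINUS)


@pytest.fixture(scope="session")
def ref_Pb(ref_rates) -> float:
    return pa.steady_state_probability(ref_rates, REF_U)


@pytest.fixture(scope="session")
def steady_states(ref_rates):
    """Steady states of the truncated system for a spread of truncation
    lengths, computed once per session (used by simulator and bound tests)."""
    out = {}
    for d in (2, 10, 25, 50, 100):
        system = pa.TruncatedSystem(d=d, rates=ref_rates, x0=pa.monomers(REF_U, d))
        out[d] = pa.steady_state(system)
    return out


@pytest.fixture(scope="session")
def trajectory_d100(ref_rates):
    system = pa.TruncatedSystem(d=100, rates=ref_rates, x0=pa.monomers(REF_U, 100))
    return pa.integrate(system, t_end=1e7)


def enumeration_rhs(x: np.ndarray, kplus: float, kminus: float) -> np.ndarray:
    """Independent RHS oracle: explicit loop over every reaction
    P_i + P_j <-> P_(i+j) with i + j <= d, applying +/- stoichiometry with
    forward rate k+ x_i x_j and reverse rate k- x_(i+j) per ordered pair
    (the doubled bookkeeping for the two identical partner roles)."""
    d = x.size
    out = np.zeros(d)
    for i in range(1, d + 1):
        for j in range(1, d + 1):
            if i + j > d:
                continue
            forward = kplus * x[i - 1] * x[j - 1]
            reverse = kminus * x[i + j - 1]
            out[i - 1] += reverse - forward
            out[j - 1] += reverse - forward
            out[i + j - 1] += forward - reverse
    return out
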