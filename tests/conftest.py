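import numpy as np
import pytest

import eetkinetics as ek
from eetkinetics.presets import WT_DE1, WT_DE2, DOMCS, DOMCS_VARIANT


@pytest.fixture(scope="session")
def de1_protocol() -> ek.Protocol:
    return ek.Protocol(e_before=-0.101, e_after=0.499)


@pytest.fixture(scope="session")
def de2_protocol() -> ek.Protocol:
    return ek.Protocol(e_before=-0.251, e_after=0.649)


@pytest.fixture(scope="session")
def de1_trace(de1_protocol) -> ek.TraceSeries:
    """Noiseless wild-type ΔE1 trace, pre-equilibrated, 10 Hz."""
    return ek.run_protocol(WT_DE1, protocol=de1_protocol)


@pytest.fixture(scope="session")
def de2_trace(de2_protocol) -> ek.TraceSeries:
    return ek.run_protocol(WT_DE2, protocol=de2_protocol)


def integrate_to_steady(p, k_i, variant="wt", t_end=None, y0=None):
    """Independent fixed-point oracle: integrate the rate equations for a
    long horizon with a high-accuracy solver and return the final state."""
    from scipy.integrate import solve_ivp

    rhs = ek.model_core.rhs_for(variant)
    if t_end is None:
        # >= 20 relaxation times of the slowest first-order scale
        slowest = min(k_i, p.k_ac)
        t_end = 20.0 / slowest
    if y0 is None:
        y0 = [0.5 * p.im_total, 0.5 * p.omc_total]
    sol = solve_ivp(
        lambda t, y: rhs(np.maximum(y, 0.0), p, k_i),
        (0.0, t_end),
        y0,
        method="LSODA",
        rtol=1e-11,
        atol=1e-12,
    )
    assert sol.success
    return sol.y[:, -1]
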