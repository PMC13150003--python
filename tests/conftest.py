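import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from r1rho import (
    DipolarPartner,
    ExchangeNetwork,
    SiteState,
    TumblingModel,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def tumbling():
    """Slow-tumbling duplex at a 600 MHz spectrometer."""
    return TumblingModel(tau_c=5.1e-9, larmor_frequency=600.16e6)


def make_two_state(p_es=0.005, kex=2000.0, dw=600.0, r1=2.5, r2=22.5):
    gs = SiteState("GS", 1.0 - p_es, 0.0, r1, r2)
    es = SiteState("ES", p_es, dw, r1, r2)
    return ExchangeNetwork([gs, es], {("GS", "ES"): kex}, topology_tag="two_state")


@pytest.fixture
def fig2_network():
    return make_two_state()


@pytest.fixture
def fig2_partner():
    return DipolarPartner(
        offset=-600.0, r1=2.5, r2=22.5, distance_per_site={"GS": 3.0, "ES": 40.0}
    )


def trott_palmer_r1rho(p_g, p_e, dw_hz, kex, r1, r2, nu_sl, carrier_hz):
    """Independent closed-form two-state R1rho (asymmetric populations,
    first-order exchange broadening) used as the oracle for the
    Bloch-McConnell eigenvalue route."""
    w1 = 2.0 * np.pi * nu_sl
    og = 2.0 * np.pi * (0.0 - carrier_hz)
    oe = 2.0 * np.pi * (dw_hz - carrier_hz)
    ob = p_g * og + p_e * oe
    weg2 = og**2 + w1**2
    wee2 = oe**2 + w1**2
    web2 = ob**2 + w1**2
    theta = np.arctan2(w1, ob)
    dw = 2.0 * np.pi * dw_hz
    rex = p_g * p_e * dw**2 * kex / (weg2 * wee2 / web2 + kex**2)
    return r1 * np.cos(theta) ** 2 + (r2 + rex) * np.sin(theta) ** 2
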