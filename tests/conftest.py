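import dataclasses

import numpy as np
import pytest

from ojipkit.petc import PROFILES, InstrumentProfile
from ojipkit.transients import AcquisitionMeta, OJIPTransient


@pytest.fixture(scope="session")
def pam_profile() -> InstrumentProfile:
    """Noiseless PAM-like acquisition (uniform 100 kHz sampling)."""
    return dataclasses.replace(PROFILES["pam-like"], noise_sigma_rel=0.0)


@pytest.fixture(scope="session")
def fast_profile() -> InstrumentProfile:
    """A light log-spaced profile for tests that don't need 64k samples."""
    return dataclasses.replace(PROFILES["pea-fine"], noise_sigma_rel=0.0)


def shoulder_transient() -> OJIPTransient:
    """Synthetic trace with an exactly known J shoulder.

    Constructed so that F0 = 1 (flat baseline), the 0.5-5 ms segment is the
    cubic 3 + 0.06 (t-2)^3 + 0.1 (t-2) — whose slope minimum (second-derivative
    root with positive third derivative) sits exactly at t = 2 ms with value
    3 — and the maximum is exactly 5, reached at t = 100 ms. The double
    normalization therefore gives V_J = (3 - 1) / (5 - 1) = 0.5.
    """
    t = np.round(np.arange(-10.0, 300.0, 0.02), 10)
    f = np.empty_like(t)
    f[t < 0] = 1.0
    cubic = lambda x: 3.0 + 0.06 * (x - 2.0) ** 3 + 0.1 * (x - 2.0)
    m_bridge = (t >= 0) & (t < 0.5)
    f[m_bridge] = 1.0 + (cubic(0.5) - 1.0) * (t[m_bridge] / 0.5)
    m_fit = (t >= 0.5) & (t <= 5.0)
    f[m_fit] = cubic(t[m_fit])
    m_rise = (t > 5.0) & (t < 100.0)
    f[m_rise] = cubic(5.0) + (5.0 - cubic(5.0)) * (t[m_rise] - 5.0) / 95.0
    f[t >= 100.0] = 5.0
    meta = AcquisitionMeta(detector_max=4095.0, baseline_ms=10.0)
    return OJIPTransient(times=t, fluorescence=f, meta=meta, trace_id="shoulder")


@pytest.fixture()
def shoulder() -> OJIPTransient:
    return shoulder_transient()
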