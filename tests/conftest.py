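import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ptycrisp as pc

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_sim():
    """Small noise-free measurement: 64x64 object, 16x16 probe, 5x5 scan."""
    return pc.simulate(pc.SimSpec(noise="clean"))


@pytest.fixture(scope="session")
def noisy_sim():
    """Same geometry at the low-dose condition with Poisson noise."""
    return pc.simulate(pc.SimSpec(dose_I0=1e8))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_dft2(a):
    """Quadratic-time unitary 2-D DFT, independent of the FFT path."""
    a = np.asarray(a, dtype=complex)
    M, N = a.shape
    out = np.zeros((M, N), dtype=complex)
    for u in range(M):
        for v in range(N):
            s = 0.0j
            for y in range(M):
                for x in range(N):
                    s += a[y, x] * np.exp(-2j * np.pi * (u * y / M + v * x / N))
            out[u, v] = s / np.sqrt(M * N)
    return out
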