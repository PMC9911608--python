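import numpy as np
import pytest

from fretclem import DecayParams


@pytest.fixture
def biexp_params():
    """Representative bi-exponential decay of a partially quenched donor."""
    return DecayParams(F0=2000.0, P1=0.4, tau1=0.8, tau2=2.6, tauG=0.15, t0=2.0)


@pytest.fixture
def tcspc_grid():
    """Default acquisition window: 12.5 ns, 256 bins."""
    edges = np.linspace(0.0, 12.5, 257)
    return edges, 0.5 * (edges[:-1] + edges[1:])


def quadrature_convolution(t, t0, tau, tauG):
    """Brute-force oracle: exponential decay convolved with a unit-area
    Gaussian via adaptive quadrature (independent of the closed form)."""
    from scipy.integrate import quad

    dt = t - t0
    val, _ = quad(
        lambda s: np.exp(-s / tau)
        * np.exp(-((dt - s) ** 2) / (2 * tauG**2))
        / np.sqrt(2 * np.pi * tauG**2),
        0.0,
        dt + 30 * tauG if dt > 0 else 30 * tauG,
        points=[max(dt, 0.0)],
        limit=400,
        epsabs=1e-30,
        epsrel=1e-10,
    )
    return val
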