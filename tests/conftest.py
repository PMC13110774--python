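import numpy as np
import pytest
from hypothesis import settings

import dimerdeer as dd

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

#: The occupancy decomposition the synthetic in vitro scenario encodes.
REFERENCE_STATE = dd.OccupancyState(0.70, 0.21, 0.09)


@pytest.fixture(scope="session")
def grid():
    return dd.DistanceGrid.regular()


@pytest.fixture(scope="session")
def time_axis():
    return dd.TimeAxis.regular(2.0, 0.008)


@pytest.fixture(scope="session")
def gaussian_25(grid):
    return dd.DistanceDistribution.gaussian(grid, 2.5, 0.1)


@pytest.fixture(scope="session")
def snr50_trace(grid, time_axis, gaussian_25):
    model = dd.TraceModel(0.18, 0.05, gaussian_25)
    return dd.simulate_trace(model, time_axis, noise_sd=0.18 / 50, seed=1)


def quadrature_kernel(time_values, r_values, n_nodes=2000):
    """Independent Pake-kernel oracle: Gauss-Legendre quadrature over the
    orientation variable, no Fresnel integrals."""
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    x = 0.5 * (x + 1.0)
    w = 0.5 * w
    omega = 2.0 * np.pi * 52.04 / np.asarray(r_values) ** 3
    phase = (3.0 * x[None, None, :] ** 2 - 1.0) * omega[None, :, None] * \
        np.asarray(time_values)[:, None, None]
    return np.einsum("k,tik->ti", w, np.cos(phase))
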