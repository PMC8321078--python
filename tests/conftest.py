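import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import lensless_qpi as q

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

WAVELENGTH = 530e-9
PIXEL = 4.65e-6


@pytest.fixture(scope="session")
def grid16():
    """Tiny grid whose 32x32 computational space suits brute-force oracles."""
    return q.make_grid(16, 16, PIXEL, WAVELENGTH)


@pytest.fixture(scope="session")
def grid256():
    return q.make_grid(256, 256, PIXEL, WAVELENGTH)


@pytest.fixture(scope="session")
def disc_phase_halfpi():
    """pi/2 binary disc phase embedded in a 256x256 sensor frame."""
    mask = q.builtin_phantom("disc", 128)
    phase = np.zeros((256, 256))
    phase[64:192, 64:192] = mask * (np.pi / 2)
    return phase


@pytest.fixture(scope="session")
def disc_retrieval_halfpi(grid256, disc_phase_halfpi):
    """Full retrieval run on the pi/2 disc under quasi-plane illumination.

    Shared by the error-reduction, convergence-curve and determinism checks
    so the 50-iteration simulation only runs once per session.
    """
    intensity = q.simulate_intensity(grid256, disc_phase_halfpi, 100.0, 0.2)
    amp = q.prepare_sensor_amplitude(intensity, grid256)
    cfg = q.RetrievalConfig(distance=0.2, max_iterations=50, stop_tolerance=0.0)
    result = q.gsa_retrieve(amp, cfg, reference_phase=q.PhaseMap(disc_phase_halfpi))
    return {"intensity": intensity, "amplitude": amp, "config": cfg,
            "result": result, "phase": disc_phase_halfpi, "grid": grid256}


def brute_force_convolution(field_values, kernel_values):
    """Direct double-sum circular convolution on center-origin arrays.

    Independent oracle for the three-FFT convolution path: for every output
    sample the sum over all input samples is accumulated explicitly, with
    the kernel indexed circularly about the grid center.
    """
    f = np.asarray(field_values)
    k = np.asarray(kernel_values)
    m, n = f.shape
    cf, ck = m // 2, n // 2
    rows, cols = np.indices((m, n))
    out = np.zeros_like(f, dtype=complex)
    for i in range(m):
        for j in range(n):
            out[i, j] = np.sum(f * k[(i - rows + cf) % m, (j - cols + ck) % n])
    return out
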