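import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import curvperm as cp

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def flat_free_model():
    """Flat landscape, constant diffusivity: pure free diffusion."""
    return cp.MembraneModel(barrier_height=0.0, d_bulk=1.0, d_mem=1.0,
                            box_half_width=50.0)


@pytest.fixture(scope="session")
def harmonic_model():
    """Diagnostic harmonic landscape G = kappa/2 z^2, constant D."""
    return cp.MembraneModel(barrier_height=0.0, quadratic_kappa=20.0,
                            d_bulk=0.5, d_mem=0.5, box_half_width=4.0)


@pytest.fixture(scope="session")
def small_flat_windows():
    """A small umbrella dataset on a gentle flat-membrane landscape.

    Shared across WHAM/diffusion/permeability tests; scaled for seconds of
    runtime while keeping adjacent-window overlap realistic.
    """
    model = cp.MembraneModel(barrier_height=10.0, well_depth=-2.0,
                             d_bulk=1.0, d_mem=0.3, box_half_width=3.0,
                             half_width=1.5, peak_width=0.8)
    centers = np.linspace(-2.6, 2.6, 15)
    windows = cp.generate_umbrella_dataset(
        model, centers, force_constant=80.0, n_steps=120_000, n_equil=5_000,
        dt=2e-4, seed=2024)
    return model, windows


@pytest.fixture(scope="session")
def harmonic_windows(harmonic_model):
    """Umbrella windows sampled on the known harmonic landscape."""
    centers = np.linspace(-1.6, 1.6, 11)
    windows = cp.generate_umbrella_dataset(
        harmonic_model, centers, force_constant=60.0, n_steps=100_000,
        n_equil=4_000, dt=2e-4, seed=7)
    return windows
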