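"""Shared fixtures: simulated scans and reference reconstructions.

The expensive end-to-end runs (200 difference-map iterations, the ML
refinement, the mixed-state pair) are session-scoped so the engine
tests and the acceptance tests share one computation.
"""

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

from ptychokit.datamodel import (
    DiffractionStack,
    ExperimentGeometry,
    ObjectStore,
    ProbeStack,
    ReconstructionState,
    ScanPositions,
    ShareMap,
)
from ptychokit.engine_dm import DMSettings, dm_iterate
from ptychokit.engine_ml import MLSettings, ml_iterate
from ptychokit.forward import exit_waves, extract_views, model_intensity
from ptychokit.simulator import SimulationSpec, initial_state, simulate_measurement

hyp_settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
hyp_settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_sim():
    """Noiseless 64x64-probe, 7x7 jittered raster at 60% overlap, seed 0."""
    spec = SimulationSpec(noise="none", seed=0)
    return simulate_measurement(spec)


@pytest.fixture(scope="session")
def dm200(noiseless_sim):
    """200 difference-map iterations from a flat object."""
    state, _ = noiseless_sim
    return dm_iterate(initial_state(state), DMSettings(n_iterations=200))


@pytest.fixture(scope="session")
def dm_ml(dm200):
    """ML refinement of the DM result down to 1e-6 normalized error."""
    return ml_iterate(dm200, MLSettings(max_iterations=80, error_target=1e-6))


@pytest.fixture(scope="session")
def mixed_sim():
    """Two-incoherent-mode simulation (0.8/0.2 energy split), noiseless."""
    spec = SimulationSpec(noise="none", seed=0, modes=2)
    return simulate_measurement(spec)


@pytest.fixture(scope="session")
def tiny_sim():
    """16x16 frames, 3x3 scan — cheap instance for gradient-level checks."""
    g = ExperimentGeometry(1e-10, 7.2, 4.5e-4, 16)
    spec = SimulationSpec(
        geometry=g,
        aperture_diameter=0.8e-6,
        defocus=5e-5,
        scan_step=4.0,
        grid_size=(3, 3),
        flux=1e4,
        noise="none",
        seed=3,
    )
    return simulate_measurement(spec)


@pytest.fixture(scope="session")
def qs_sweep_rows():
    """Quality-vs-QS sweep on a Poisson-limited simulation (shared)."""
    from ptychokit.compression import qs_quality_sweep

    spec = SimulationSpec(noise="poisson", seed=0, flux=1e6)
    state, truth = simulate_measurement(spec)
    return qs_quality_sweep(state, truth, [0, 0.25, 0.5, 1, 2, 4], dm_iterations=100)


def make_manual_state(n=4, n_positions=1, seed=5, n_modes=1, step=2):
    """Hand-rolled tiny consistent state: random probe/object, exact data."""
    rng = np.random.default_rng(seed)
    geometry = ExperimentGeometry(1e-10, 1.0, 1e-10 / n, n)
    # probe magnitudes bounded away from zero: every pixel is informative
    probe = ProbeStack(
        rng.uniform(0.5, 1.5, (n, n, 1, n_modes))
        * np.exp(2j * np.pi * rng.random((n, n, 1, n_modes)))
    )
    extent = n + step * n_positions
    obj = rng.standard_normal((extent, extent)) + 1j * rng.standard_normal(
        (extent, extent)
    )
    objects = ObjectStore({1: obj[:, :, None, None]})
    pos = np.column_stack(
        [np.arange(n_positions) * step, np.arange(n_positions) * step]
    ).astype(float)
    positions = ScanPositions(pos, np.zeros(n_positions, int))
    share = ShareMap([1], [1])
    views = exit_waves(probe, extract_views(objects, positions, share, (n, n)), share)
    data = DiffractionStack(model_intensity(views), np.ones((n, n), bool), geometry)
    return ReconstructionState(
        geometry=geometry,
        data=data,
        positions=positions,
        probes=probe,
        objects=objects,
        share=share,
    )


@pytest.fixture
def manual_state():
    return make_manual_state()
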