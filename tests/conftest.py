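"""Shared fixtures.

The expensive end-to-end desk experiment (simulate paired datasets,
train both networks, extrapolate, invert all four dataset variants over
three phantom seeds) runs once per session; the cycle-skipping and
bandwidth-extension assertions all read from its results.
"""

import numpy as np
import pytest

from usctfwi.phantom import homogeneous_model, make_breast_phantom
from usctfwi.presets import DESK
from usctfwi.wavesim import SimParams, WaveSolver


@pytest.fixture(scope="session")
def desk():
    return DESK


@pytest.fixture(scope="session")
def desk_geometry():
    return DESK.geometry()


@pytest.fixture(scope="session")
def desk_phantom():
    return make_breast_phantom(DESK.phantom_spec(0), DESK.grid_shape, DESK.spacing)


@pytest.fixture(scope="session")
def desk_experiment(tmp_path_factory):
    """Full three-seed desk study; shared by the cycle-skipping and
    bandwidth-extension tests."""
    from usctfwi.pipeline import ExperimentConfig, run_experiment

    outdir = tmp_path_factory.mktemp("experiment")
    config = ExperimentConfig(seed=0, outdir=str(outdir))
    return run_experiment(config)


@pytest.fixture(scope="session")
def water_solver_fine():
    """Homogeneous water solver at >= 8 points per wavelength for the
    travel-time and boundary-quality physics checks."""
    spacing = 0.8e-3  # 8 ppw at 232 kHz in water
    model = homogeneous_model((192, 192), spacing)
    params = SimParams(t_max=160e-6, output_dt=1e-6, boundary_width=25,
                       f_max=230e3, ppw_min=8.0)
    return model, WaveSolver(model, params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
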