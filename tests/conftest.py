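"""Shared fixtures: a coarse full-geometry environment and small solver models."""

import numpy as np
import pytest

from tenssim.experiments import SimulationEnvironment
from tenssim.geometry import ElectrodeArray, FingerGeometry, TissueConductivities
from tenssim.volume_conductor import NailPatch, build_finger_model


@pytest.fixture(scope="session")
def coarse_env():
    """Full study geometry on a coarse (0.9 mm) grid: fast, qualitatively
    faithful; used wherever the test checks structure rather than converged
    field values."""
    return SimulationEnvironment(resolution=0.9e-3)


@pytest.fixture(scope="session")
def small_model():
    """Miniature finger (12 mm diameter, 30 mm long, 4 electrodes) for cheap
    solver property tests."""
    geometry = FingerGeometry(
        finger_diameter=0.012, bone_diameter=0.003, skin_thickness=0.0015,
        finger_length=0.03,
    )
    array = ElectrodeArray(
        n_electrodes=4, electrode_width=0.0016, electrode_length=0.006,
        pitch=0.003, longitudinal_offset=0.008,
    )
    nail = NailPatch(x_start=0.002, length=0.008, width=0.006)
    return build_finger_model(geometry, TissueConductivities(), array,
                              resolution=0.0015, nail=nail)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
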