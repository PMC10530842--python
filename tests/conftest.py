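import warnings

import numpy as np
import pytest

from cryogel.imaging import CameraModel
from cryogel.solver import ProcessConfig, run_simulation

#: bath set points studied in the reference process, with enough simulated
#: time for full solidification plus the post-freeze decay
BATHS = {-25.0: 1200.0, -19.0: 1200.0, -12.0: 1500.0}


@pytest.fixture(scope="session")
def sim_results():
    """Freezing simulations at the three studied bath set points."""
    out = {}
    for bath, total in BATHS.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[bath] = run_simulation(
                ProcessConfig(bath_setpoint_C=bath, total_time=total)
            )
    return out


@pytest.fixture(scope="session")
def camera():
    """Pinhole camera: 40 px/mm at the symmetry plane, 300 mm working distance."""
    return CameraModel(base_scale=40.0, working_distance=300.0)


@pytest.fixture(scope="session")
def quick_config():
    """Small, fast configuration for smoke tests (does not fully freeze)."""
    return ProcessConfig(total_time=30.0, dt=1.0, grid_size=0.002)


def interp_theta(result, r, z):
    """Interpolated solid-fraction series at a probe point."""
    from cryogel.solver import _probe_weights

    cells, w = _probe_weights(result.grid, result.config, r, z, result.cryogel_cells)
    cols = np.array([int(np.flatnonzero(result.cryogel_cells == c)[0]) for c in cells])
    return result.theta_history[:, cols] @ w
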