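"""Shared fixtures: small head/montage/lead-field instances reused across
modules (session-scoped; the lead field is the only expensive object)."""

import numpy as np
import pytest

from hdesi import forward as fwd
from hdesi import simulate as sim


@pytest.fixture(scope="session")
def head():
    return fwd.ThreeShellHeadModel()


@pytest.fixture(scope="session")
def head_homogeneous():
    return fwd.ThreeShellHeadModel(conductivities_S_per_m=(0.33, 0.33, 0.33))


@pytest.fixture(scope="session")
def electrodes64():
    return fwd.build_electrode_array(64, 140)


@pytest.fixture(scope="session")
def grid12(head):
    return fwd.build_source_grid(head, 12.0)


@pytest.fixture(scope="session")
def leadfield64(head, electrodes64, grid12):
    return fwd.compute_leadfield(head, electrodes64, grid12, n_terms=60)


@pytest.fixture(scope="session")
def template250():
    return sim.generate_ied_template(250)


@pytest.fixture(scope="session")
def source_index(grid12):
    """A lateral, fairly superficial grid point used as the standard source."""
    target = np.array([48.0, 0.0, 24.0])
    return int(np.argmin(np.linalg.norm(grid12.positions - target, axis=1)))


@pytest.fixture(scope="session")
def recording(leadfield64, template250, source_index):
    """Default spike-bearing recording shared by detection/epoching tests."""
    return sim.simulate_recording(
        leadfield64,
        template250,
        n_events=12,
        event_grid_index=source_index,
        amplitude_nAm=750.0,
        jitter_amplitude_frac=0.1,
        noise_rms_uV=15.0,
        duration_s=60.0,
        seed=99,
    )
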