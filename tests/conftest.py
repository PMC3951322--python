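import numpy as np
import pytest

from laminar_ephys import (
    ProbeGeometry,
    StimulusProtocol,
    control_like_profile,
    default_component_catalogue,
    segment_sweeps,
)
from laminar_ephys.synthetic import simulate_protocol


@pytest.fixture(scope="session")
def geometry():
    return ProbeGeometry(n_contacts=16, spacing_um=100.0)


@pytest.fixture(scope="session")
def geometry32():
    return ProbeGeometry(n_contacts=32, spacing_um=50.0)


@pytest.fixture(scope="session")
def catalogue():
    return default_component_catalogue()


@pytest.fixture(scope="session")
def clean_pair_recording(geometry):
    """Noise-free, artifact-free paired-pulse recording (unit P2 gain)."""
    profile = control_like_profile()
    proto = StimulusProtocol(kind="paired_pulse", ppi_ms=200, n_repeats=3)
    return simulate_protocol(
        profile, proto, geometry, noise_sd=0.0, artifact_amp=0.0, seed=11
    )


@pytest.fixture(scope="session")
def clean_pair_sweeps(clean_pair_recording):
    return segment_sweeps(clean_pair_recording)


@pytest.fixture(scope="session")
def noisy_pair_recording(geometry):
    profile = control_like_profile()
    proto = StimulusProtocol(kind="paired_pulse", ppi_ms=200, n_repeats=20)
    return simulate_protocol(
        profile, proto, geometry, noise_sd=0.05, artifact_amp=5.0, seed=12
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
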