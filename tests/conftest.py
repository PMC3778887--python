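import numpy as np
import pytest

from sdcm.inference import InversionSettings, invert_deterministic
from sdcm.model_core import pack_parameters
from sdcm.simulator import add_measurement_noise, fixture_network, integrate


@pytest.fixture(scope="session")
def linear_fixture():
    return fixture_network("linear_2r")


@pytest.fixture(scope="session")
def linear_traj(linear_fixture):
    spec, inp, settings = linear_fixture
    return integrate(spec, inp, settings)


@pytest.fixture(scope="session")
def recovery_runs(linear_fixture, linear_traj):
    """Twenty seeded deterministic inversions of the linear two-region
    network at 10 dB measurement SNR (10-minute sessions), shared by the
    recovery and calibration checks."""
    spec, inp, _ = linear_fixture
    theta_true, imap = pack_parameters(spec)
    posts = []
    for seed in range(20):
        y = add_measurement_noise(linear_traj.y_clean, 10.0, seed=seed)
        posts.append(invert_deterministic(
            spec, y, inp, TR=1.0, settings=InversionSettings(dt=1 / 16)))
    a_idx = [i for i, (block, _) in enumerate(imap.entries) if block == "A"]
    return {"posteriors": posts, "theta_true": theta_true,
            "index_map": imap, "a_idx": np.array(a_idx)}
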