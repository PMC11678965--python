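from dataclasses import replace

import numpy as np
import pytest

from tuglab import segment, synth


@pytest.fixture(scope="session")
def profiles():
    return synth.load_group_profiles()


@pytest.fixture(scope="session")
def control_params(profiles):
    return profiles["control"]


@pytest.fixture(scope="session")
def severe_params(profiles):
    return profiles["severe"]


@pytest.fixture(scope="session")
def noiseless_control(control_params):
    return replace(control_params, noise_sd_g=0.0)


@pytest.fixture(scope="session")
def tug_recording(control_params):
    return synth.simulate_recording(control_params, "TUG", 1, seed=1, participant_id="c001")


@pytest.fixture(scope="session")
def tug_segmented(tug_recording):
    return segment.segment_tug(tug_recording)


@pytest.fixture(scope="session")
def walk32_recording(control_params):
    return synth.simulate_recording(control_params, "walk32ft", 1, seed=7, participant_id="c007")


def truth_bounds(rec) -> dict[str, tuple[int, int]]:
    return {label: (s, e) for label, s, e in rec.truth["segments"]}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
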