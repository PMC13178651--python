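import numpy as np
import pytest

from airglt import airway, simulate, tracks


@pytest.fixture(scope="session")
def default_tree():
    return airway.build_weibel_tree()


@pytest.fixture(scope="session")
def rest_flow():
    return airway.FlowCondition.from_lpm(15.0, "rest")


@pytest.fixture(scope="session")
def exercise_flow():
    return airway.FlowCondition.from_lpm(75.0, "exercise")


@pytest.fixture
def protocol():
    return tracks.PulseProtocol()


def make_linear_track(track_id="0", velocity=(0.0, 0.0), origin=(0.0, 0.0),
                      t_start=0.0, t_end=15.0, frame_rate=10.0):
    """Constant-velocity track sampled at frame_rate, for analytic checks."""
    n = int(round((t_end - t_start) * frame_rate)) + 1
    t = t_start + np.arange(n) / frame_rate
    return tracks.Track(
        track_id=track_id,
        frame=np.arange(n),
        t=t,
        x=origin[0] + velocity[0] * (t - t_start),
        y=origin[1] + velocity[1] * (t - t_start),
    )


@pytest.fixture
def noiseless_track_params(protocol):
    return simulate.TrackSimParams(
        n_beads=5,
        drift=(0.0, 0.0),
        localization_noise_sd=0.0,
        protocol=protocol,
        seed=42,
    )
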