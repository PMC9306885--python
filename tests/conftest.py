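import numpy as np
import pytest

from vigilpupil import preprocess, schedule, synthetic


@pytest.fixture(scope="session")
def exp1_schedule():
    return schedule.generate_vigilance_schedule(seed=1)


@pytest.fixture(scope="session")
def short_schedule():
    """Six-minute vigilance schedule for cheap full-chain tests."""
    return schedule.generate_vigilance_schedule(duration_min=6, seed=3)


@pytest.fixture(scope="session")
def pvt_schedule():
    return schedule.generate_pvt_schedule(seed=7)


@pytest.fixture(scope="session")
def short_session(short_schedule):
    """One simulated six-minute session, raw and preprocessed."""
    obs = synthetic.ObserverParams()
    responses, truth = synthetic.simulate_behavior(short_schedule, obs, seed=21)
    t, pupil, gx, gy = synthetic.simulate_pupil(
        short_schedule, responses, truth, synthetic.PupilParams(), 250, seed=22
    )
    raw = preprocess.SampleSeries(250, float(t[0]), pupil, gx, gy)
    low, z = preprocess.preprocess_session(raw)
    return dict(schedule=short_schedule, responses=responses, truth=truth,
                raw=raw, series_au=low, series_z=z)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
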