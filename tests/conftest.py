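import numpy as np
import pytest

from thetacode import synth
from thetacode.preprocess import binarize_traces


@pytest.fixture(scope="session")
def clean_track_cfg():
    """Stereotyped session: no errors, no pauses, no wander, fixed speed."""
    return synth.TrackConfig(
        n_runs=8, mean_speed=20.0, speed_cv=0.0, pause_range=(0.0, 0.0),
        error_rate=0.0, false_start_prob=0.0, hesitation_rate=0.0,
        wander_speed=0.0, slow_departure_prob=0.0, exploration_rate=0.0,
        rest_rate=0.0, partial_reversal_rate=0.0, trial_pace_sd=0.0,
    )


@pytest.fixture(scope="session")
def clean_session(clean_track_cfg):
    return synth.simulate_track_session(clean_track_cfg, seed=0)


@pytest.fixture(scope="session")
def track_session():
    """A default (non-stereotyped) session, moderately sized."""
    return synth.simulate_track_session(synth.TrackConfig(n_runs=32), seed=7)


@pytest.fixture(scope="session")
def tuned_population(track_session):
    rng = np.random.default_rng(21)
    specs = synth.make_population(10, 6, 6, 8, rng)
    neural, truth = synth.simulate_neurons(track_session, specs, seed=13)
    binary = binarize_traces(neural.traces, track_session.frame_rate)
    return specs, neural, truth, binary
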