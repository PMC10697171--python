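import numpy as np
import pytest

from palpebra.detection import SegmentationParams, classify_blinks, detect_blink_periods
from palpebra.synthetic import SimulationConfig, simulate_recording, simulate_study
from palpebra.trace_io import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def baseline_recording():
    return Recording(
        recording_id="P001_left_baseline",
        participant_id="P001",
        eye="left",
        condition="baseline",
        volitional_start=60.0,
    )


@pytest.fixture
def noisefree_config():
    return SimulationConfig(noise_sd_mm=0.0, seed=7)


@pytest.fixture
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture
def small_study():
    """A small complete study: 6 participants, no missing conditions."""
    cfg = SimulationConfig(n_participants=6, missing_fraction=0.0,
                           p_bilateral=0.0, seed=11)
    recordings, traces, truth = simulate_study(cfg)
    return cfg, recordings, traces, truth


def segmented(recordings, traces, params=SegmentationParams()):
    """Detect + classify every recording; yields table-builder triples."""
    for rec in recordings:
        trace = traces[rec.recording_id]
        seg = classify_blinks(detect_blink_periods(trace, params), rec, trace)
        yield rec, trace, seg
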