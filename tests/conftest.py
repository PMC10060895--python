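import numpy as np
import pytest

import spikefbn as sf
from spikefbn.pipeline import detect_candidates


@pytest.fixture(scope="session")
def fs() -> float:
    return 1000.0


@pytest.fixture(scope="session")
def sim_config() -> sf.SimulationConfig:
    return sf.SimulationConfig(duration=60.0, n_spikes=12, seed=3)


@pytest.fixture(scope="session")
def simulated(sim_config):
    """One shared simulated recording with ground truth."""
    recording, annotations = sf.simulate(sim_config)
    return recording, annotations


@pytest.fixture(scope="session")
def av_bp(simulated):
    recording, _ = simulated
    filtered = sf.bandpass(recording)
    return sf.to_average_reference(filtered), sf.to_bipolar(filtered)


@pytest.fixture(scope="session")
def detected(av_bp, simulated):
    """Candidates + truth labels on the shared recording."""
    av, _ = av_bp
    _, annotations = simulated
    candidates, counts = detect_candidates(av, sf.MatchConfig())
    labels = sf.label_candidates(candidates, annotations, tolerance_ms=60.0)
    return candidates, labels, counts


def triangle_frame(amplitude=300.0, duration_ms=60.0, fs=1000.0, win_ms=300.0,
                   sign=1.0):
    """A window-length frame holding a centered triangle."""
    win = int(round(win_ms * fs / 1000.0))
    tri = sf.make_spike_waveform(amplitude, duration_ms, fs) * sign
    frame = np.zeros(win)
    start = win // 2 - (len(tri) - 1) // 2
    frame[start : start + len(tri)] = tri
    return frame


def make_candidate(frame, apex_index=None, channel="C3", fs=1000.0,
                   correlation=1.0, template_id="universal"):
    """A CandidateSpike wrapping a constructed frame (apex at the center)."""
    win = len(frame)
    if apex_index is None:
        apex_index = win // 2
    return sf.CandidateSpike(
        av_channel=channel, apex_index=apex_index, frame=np.asarray(frame),
        frame_start=apex_index - win // 2, correlation=correlation,
        template_id=template_id, fs=fs,
    )
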