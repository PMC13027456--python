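import numpy as np
import pytest

from qeegdep import SegmentLabel, SegmentRecording
from qeegdep.session import DEFAULT_REGION_MAP


def make_segment(label=SegmentLabel.BACKGROUND, duration=60.0, fs=250.0,
                 channels=("FZ-CZ",), signal_fn=None, seed=0):
    """Segment with a caller-supplied signal function of the time vector."""
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    t = np.arange(n) / fs
    rows = []
    for _ in channels:
        if signal_fn is None:
            rows.append(rng.normal(0, 1, n))
        else:
            rows.append(signal_fn(t, rng))
    return SegmentRecording(label=label, sampling_rate=fs,
                            channel_labels=list(channels),
                            samples=np.vstack(rows))


@pytest.fixture
def tone_segment():
    """Unit-amplitude 10 Hz sinusoid, 60 s at 250 Hz, one channel."""
    return make_segment(signal_fn=lambda t, rng: np.sin(2 * np.pi * 10 * t))


@pytest.fixture(scope="session")
def healthy_session():
    from qeegdep import generate_session

    return generate_session("healthy", subject_id="h0", seed=11,
                            duration_scale=0.2)


@pytest.fixture(scope="session")
def dependent_session():
    from qeegdep import generate_session

    return generate_session("hyperaroused_dependent", subject_id="d0",
                            seed=12, duration_scale=0.2)


@pytest.fixture(scope="session")
def all_derivations():
    return list(DEFAULT_REGION_MAP)
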