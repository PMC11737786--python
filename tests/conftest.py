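import numpy as np
import pytest

from emdpcnn.io import RawRecording
from emdpcnn.synthetic import write_edf


@pytest.fixture(scope="session")
def edf_fixture(tmp_path_factory):
    """A small 2-channel, 250 Hz EDF+ recording with 3 known markers.

    Returns (path, reference RawRecording); the writer is the oracle for
    the reader round-trip.
    """
    rng = np.random.default_rng(42)
    samples = rng.normal(scale=20.0, size=(2, 2500))
    rec = RawRecording(
        samples=samples,
        rate=250.0,
        channel_labels=["C3", "C4"],
        events=[(125, 769), (750, 770), (2000, 769)],
    )
    path = tmp_path_factory.mktemp("io") / "fixture.edf"
    write_edf(path, rec)
    return path, rec


@pytest.fixture(scope="session")
def two_tone_signal():
    """sin(2*pi*2t) + sin(2*pi*20t) at 250 Hz for 4 s, plus the components."""
    t = np.arange(0, 4, 1 / 250)
    lo = np.sin(2 * np.pi * 2 * t)
    hi = np.sin(2 * np.pi * 20 * t)
    return lo + hi, hi, lo
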