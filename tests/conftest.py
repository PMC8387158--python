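import numpy as np
import pytest

from stimbox.playframe import PlayEntry, Playframe
from stimbox.stimulus_io import Stimulus, make_tone, save_stimulus


@pytest.fixture
def stereo_tone() -> Stimulus:
    return make_tone(1000.0, 200.0, 44_100, amplitude=0.9)


@pytest.fixture
def stim_dir(tmp_path, stereo_tone):
    """A 'stim' folder holding one valid stereo 44.1 kHz WAV (beep.wav)."""
    d = tmp_path / "stim"
    d.mkdir()
    save_stimulus(stereo_tone, d / "beep.wav")
    return d


@pytest.fixture
def mono_wav(stim_dir):
    mono = Stimulus(np.zeros((4410, 1)) + 0.5, 44_100, name="mono")
    path = stim_dir / "mono.wav"
    save_stimulus(mono, path)
    return path


@pytest.fixture
def wrong_rate_wav(stim_dir):
    tone = make_tone(1000.0, 100.0, 48_000, amplitude=0.5)
    path = stim_dir / "hirate.wav"
    save_stimulus(tone, path)
    return path


@pytest.fixture
def two_entry_playframe() -> Playframe:
    return Playframe(
        [PlayEntry("beep.wav", 255, 500.0), PlayEntry("beep.wav", 12, 1000.0)]
    )
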