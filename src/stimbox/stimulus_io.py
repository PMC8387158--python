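"""WAV stimulus reading/writing, tone synthesis, calibration protocols.

Protocol stimuli are stereo PCM WAV files at 44,100 Hz.  In memory a stimulus
is float amplitude in [-1, 1]; on disk it is 16-bit PCM (integer samples are
rescaled on load, so a save/load roundtrip is the identity up to one 16-bit
quantization step of 2**-15 per sample).

The calibration protocol reproduces the standard loopback timing test:
a 1000 Hz, 200 ms tone repeated 1000 times, each presentation marked with
trigger value 255.
"""

from __future__ import annotations

import os
import wave
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from stimbox.errors import StimulusError
from stimbox.playframe import Playframe

#: Calibration-protocol defaults (the loopback benchmark signal).
CALIBRATION_TONE_HZ = 1000.0
CALIBRATION_DURATION_MS = 200.0
CALIBRATION_SAMPLE_RATE_HZ = 44_100
CALIBRATION_TRIGGER_VALUE = 255
CALIBRATION_N_REPEATS = 1000
CALIBRATION_ISI_MS = 500.0
CALIBRATION_TONE_NAME = "calibration_tone.wav"

_PCM16_SCALE = 32767.0


@dataclass
class Stimulus:
    """A two-channel audio stimulus held as float amplitude.

    ``samples`` has shape (n, 2) with values in [-1, 1]; channel count other
    than 2 is representable (so a mono file can be loaded and then flagged by
    validation) but violates the protocol invariant.
    """

    samples: np.ndarray
    sample_rate_hz: float
    name: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, np.newaxis]
        if self.sample_rate_hz <= 0:
            raise StimulusError(f"sample rate must be > 0, got {self.sample_rate_hz}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.sample_rate_hz


def read_wav_header(path: str | os.PathLike) -> tuple[int, int, int]:
    """Return (sample_rate_hz, n_channels, n_frames) from a WAV header.

    Reads only the header, so it is safe to run over a whole stimulus folder.
    """
    with wave.open(str(path), "rb") as wav:
        return wav.getframerate(), wav.getnchannels(), wav.getnframes()


def load_stimulus(path: str | os.PathLike) -> Stimulus:
    """Load a PCM WAV file, rescaling integer samples to [-1, 1]."""
    p = Path(path)
    try:
        rate, data = wavfile.read(p)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise StimulusError(f"{p}: cannot read WAV ({exc})") from exc
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / _PCM16_SCALE
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483647.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 127.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise StimulusError(f"{p}: unsupported sample encoding {data.dtype}")
    return Stimulus(samples, float(rate), name=p.name)


def save_stimulus(stim: Stimulus, path: str | os.PathLike) -> None:
    """Write a stimulus as 16-bit PCM WAV at its own sample rate."""
    clipped = np.clip(stim.samples, -1.0, 1.0)
    pcm = np.round(clipped * _PCM16_SCALE).astype(np.int16)
    wavfile.write(str(path), int(round(stim.sample_rate_hz)), pcm)


def make_tone(
    freq_hz: float = CALIBRATION_TONE_HZ,
    duration_ms: float = CALIBRATION_DURATION_MS,
    sample_rate_hz: float = CALIBRATION_SAMPLE_RATE_HZ,
    amplitude: float = 0.9,
) -> Stimulus:
    """Synthesize a stereo phase-0 sine tone.

    Both channels carry the same sine starting at phase 0 (first sample is
    exactly 0), with no onset/offset ramp: the loopback measurement detects
    the first supra-threshold sample, and a ramp would bias that onset.
    """
    if freq_hz <= 0 or duration_ms <= 0 or sample_rate_hz <= 0:
        raise StimulusError("frequency, duration and rate must all be positive")
    if not 0 <= amplitude <= 1:
        raise StimulusError(f"amplitude must be in [0, 1], got {amplitude}")
    n = int(round(duration_ms * sample_rate_hz / 1000.0))
    t = np.arange(n) / sample_rate_hz
    mono = amplitude * np.sin(2.0 * np.pi * freq_hz * t)
    samples = np.column_stack([mono, mono])
    return Stimulus(samples, sample_rate_hz, name=f"tone_{freq_hz:g}Hz_{duration_ms:g}ms")


def make_calibration_protocol(
    n_repeats: int = CALIBRATION_N_REPEATS,
    trigger_value: int = CALIBRATION_TRIGGER_VALUE,
    isi_ms: float | tuple[float, float] = CALIBRATION_ISI_MS,
    out_dir: str | os.PathLike = ".",
    seed: int = 0,
) -> Playframe:
    """Build the loopback calibration protocol and write its tone to disk.

    Writes the calibration tone (1000 Hz, 200 ms, 44,100 Hz stereo WAV) into
    ``out_dir/stim`` and returns a playframe of ``n_repeats`` identical
    entries referencing it with the given trigger marker.  ``isi_ms`` may be
    a fixed value (default 500 ms) or a (low, high) range of seeded uniform
    draws for a moving-ISI variant.
    """
    if n_repeats < 1:
        raise ValueError(f"n_repeats must be >= 1, got {n_repeats}")
    stim_dir = Path(out_dir) / "stim"
    stim_dir.mkdir(parents=True, exist_ok=True)
    tone = make_tone()
    save_stimulus(tone, stim_dir / CALIBRATION_TONE_NAME)
    from stimbox.playframe import generate_playframe

    return generate_playframe(
        [CALIBRATION_TONE_NAME] * n_repeats,
        [trigger_value] * n_repeats,
        isi_ms,
        order="as_given",
        seed=seed,
    )
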