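"""Synthetic loopback recordings with known injected timing.

Renders an :class:`~stimbox.scheduler.EventLog` into the two-channel signal a
physical loopback cable would deliver: a rectangular pulse on the trigger
channel at each trigger onset, a copy of the test tone on the audio channel at
each sound onset, both on one shared clock.  Because the injected latency and
jitter are known exactly, the whole measurement chain can be validated without
hardware: render a run, analyze it, and compare recovered parameters with the
injected ones.

Only timing is rendered — the trigger value collapses to pulse presence, since
the loopback method measures *when* the lines went high, not which ones
(value fidelity is the encoder's job).  No analog effects (rise time, cable
capacitance, anti-aliasing) are modeled.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field

import numpy as np

from stimbox.scheduler import (
    DEFAULT_TRIGGER_PULSE_MS,
    EventLog,
    NoiseModel,
    SimulatedBackend,
    compile_schedule,
    run_schedule,
)
from stimbox.stimulus_io import (
    CALIBRATION_SAMPLE_RATE_HZ,
    Stimulus,
    make_calibration_protocol,
    make_tone,
    save_stimulus,
)
from stimbox.timing_analysis import LoopbackRecording

#: Silence appended after the last event so final tones/pulses render fully.
TAIL_MS = 500.0


@dataclass
class RenderParams:
    """How an event log is turned into a two-channel recording.

    ``tone`` is the stimulus copied onto the audio channel at every sound
    onset (default: the calibration tone); its left channel is used.
    ``noise_sd`` adds seeded zero-mean Gaussian amplitude noise to both
    channels, emulating capture noise.
    """

    sample_rate_hz: float = float(CALIBRATION_SAMPLE_RATE_HZ)
    trigger_pulse_ms: float = DEFAULT_TRIGGER_PULSE_MS
    trigger_amplitude: float = 1.0
    tone: Stimulus | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trigger_pulse_ms <= 0:
            raise ValueError(
                f"trigger pulse width must be > 0, got {self.trigger_pulse_ms}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise SD must be >= 0, got {self.noise_sd}")

    def resolved_tone(self) -> Stimulus:
        return self.tone if self.tone is not None else make_tone()


def _place(buffer: np.ndarray, start: int, chunk: np.ndarray) -> None:
    """Add ``chunk`` into ``buffer`` at ``start``, clipping to the buffer."""
    if start >= buffer.size:
        return
    lo = max(start, 0)
    hi = min(start + chunk.size, buffer.size)
    if hi <= lo:
        return
    buffer[lo:hi] += chunk[lo - start : hi - start]


def render_loopback(log: EventLog, params: RenderParams | None = None) -> LoopbackRecording:
    """Render an event log into a loopback recording.

    The trigger channel carries one rectangular pulse per ``trigger_onset``
    record; the audio channel carries one tone copy per ``sound_onset``.
    Overlapping events are summed then clipped to [-1, 1].  Deterministic
    given the parameter seed; a zero-length log yields a minimal silent
    recording.
    """
    if params is None:
        params = RenderParams()
    rate = params.sample_rate_hz
    tone = params.resolved_tone()
    if abs(tone.sample_rate_hz - rate) > 1e-9:
        raise ValueError(
            f"tone rate {tone.sample_rate_hz} Hz differs from render rate {rate} Hz"
        )
    tone_mono = tone.samples[:, 0]
    # Align the tone's first observable (nonzero) sample to the onset index:
    # a phase-0 sine starts at an exact zero crossing, which no threshold
    # detector can see, so leading zero samples would shift every measured
    # sound onset late by their count.
    nonzero = np.flatnonzero(tone_mono)
    tone_mono = tone_mono[nonzero[0] :] if nonzero.size else tone_mono
    pulse_n = int(round(params.trigger_pulse_ms * rate / 1000.0))
    pulse = np.full(pulse_n, params.trigger_amplitude)

    trig_times = log.times("trigger_onset")
    sound_times = log.times("sound_onset")
    last_ms = 0.0
    if trig_times.size:
        last_ms = max(last_ms, trig_times.max() + params.trigger_pulse_ms)
    if sound_times.size:
        last_ms = max(last_ms, sound_times.max() + tone.duration_ms)
    n = int(round((last_ms + TAIL_MS) * rate / 1000.0)) + 1

    audio = np.zeros(n)
    trigger = np.zeros(n)
    for t in sound_times:
        _place(audio, int(round(t * rate / 1000.0)), tone_mono)
    for t in trig_times:
        _place(trigger, int(round(t * rate / 1000.0)), pulse)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        audio += rng.normal(0.0, params.noise_sd, n)
        trigger += rng.normal(0.0, params.noise_sd, n)
    np.clip(audio, -1.0, 1.0, out=audio)
    np.clip(trigger, -1.0, 1.0, out=trigger)
    return LoopbackRecording(audio, trigger, rate)


def render_calibration(
    n_repeats: int = 1000,
    trigger_value: int = 255,
    isi_ms: float | tuple[float, float] = 500.0,
    noise: NoiseModel | None = None,
    params: RenderParams | None = None,
) -> LoopbackRecording:
    """Run the full loopback benchmark in one call.

    Builds the calibration protocol, compiles it, executes it on the
    simulated backend under ``noise``, and renders the resulting event log.
    Reproducible from the noise and render seeds.
    """
    if params is None:
        params = RenderParams()
    if noise is None:
        noise = NoiseModel()
    with tempfile.TemporaryDirectory() as tmp:
        pf = make_calibration_protocol(
            n_repeats=n_repeats,
            trigger_value=trigger_value,
            isi_ms=isi_ms,
            out_dir=tmp,
            seed=noise.seed,
        )
    tone = params.resolved_tone()
    schedule = compile_schedule(pf, [tone.duration_ms] * len(pf), params.sample_rate_hz)
    log = run_schedule(schedule, SimulatedBackend(noise))
    return render_loopback(log, params)


def write_loopback_wav(rec: LoopbackRecording, path) -> None:
    """Save a recording as a standard 2-channel 16-bit WAV fixture."""
    stim = Stimulus(
        np.column_stack([rec.audio_channel, rec.trigger_channel]),
        rec.sample_rate_hz,
        name="loopback",
    )
    save_stimulus(stim, path)
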