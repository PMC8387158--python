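"""Schedule compilation, trigger encoding, and protocol execution.

A playframe plus per-entry stimulus durations compiles into an absolute-time
:class:`Schedule`: entry 0 starts at 0 ms and each subsequent onset follows
``onset(i+1) = onset(i) + duration(i) + isi(i)`` exactly (offset-to-onset ISI
semantics).

Execution is split from output: :func:`run_schedule` drives an abstract
:class:`Backend` which starts sounds and asserts trigger words, and returns an
:class:`EventLog` of timestamped events.  The shipped reference backend is
purely simulated — it applies a :class:`NoiseModel` (constant latencies plus
seeded Gaussian jitter) to the scheduled times, so runs are deterministic and
the whole loopback validation chain can be exercised without hardware.

Trigger markers are encoded onto 8 digital output lines (the parallel-port
data lines EEG amplifiers read), line k carrying bit k of the value
(LSB-first), giving the full 2**8 = 256 distinct marker states.
"""

from __future__ import annotations

import csv
import io
import math
import os
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from stimbox.errors import BackendError, ScheduleError, TriggerEncodingError
from stimbox.playframe import Playframe

#: Number of digital output lines available for markers.
N_TRIGGER_LINES = 8

#: Default width of the asserted trigger pulse before reset to 0.
DEFAULT_TRIGGER_PULSE_MS = 10.0

#: Number of progress indicator levels (LED bar on the physical box).
DEFAULT_PROGRESS_LEVELS = 5


# ---------------------------------------------------------------------------
# schedule compilation


@dataclass(frozen=True)
class ScheduledEvent:
    """One protocol entry placed on the absolute timeline."""

    index: int
    onset_ms: float
    duration_ms: float
    trigger_value: int
    isi_ms: float

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms


@dataclass
class Schedule:
    """Absolute-time compilation of a playframe."""

    events: list[ScheduledEvent] = field(default_factory=list)
    sample_rate_hz: float = 44_100.0

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def total_duration_ms(self) -> float:
        """End of the last stimulus (final ISI excluded); 0 when empty."""
        if not self.events:
            return 0.0
        return self.events[-1].offset_ms


def compile_schedule(
    pf: Playframe,
    durations_ms: Sequence[float],
    sample_rate_hz: float = 44_100.0,
) -> Schedule:
    """Compile a playframe into absolute onset times.

    ``durations_ms`` supplies each entry's stimulus duration (one value per
    entry, non-negative).  The recurrence is exact in the arithmetic of the
    inputs: integer-valued durations and ISIs give integer-valued onsets.
    """
    if len(durations_ms) != len(pf):
        raise ScheduleError(
            f"{len(durations_ms)} durations for {len(pf)} entries"
        )
    events: list[ScheduledEvent] = []
    onset = 0.0
    for i, (entry, dur) in enumerate(zip(pf.entries, durations_ms)):
        dur = float(dur)
        if dur < 0 or not math.isfinite(dur):
            raise ScheduleError(f"entry {i}: duration {dur} must be finite and >= 0")
        events.append(
            ScheduledEvent(
                index=i,
                onset_ms=onset,
                duration_ms=dur,
                trigger_value=entry.trigger_value,
                isi_ms=entry.isi_ms,
            )
        )
        onset = onset + dur + entry.isi_ms
    return Schedule(events, sample_rate_hz=float(sample_rate_hz))


# ---------------------------------------------------------------------------
# trigger words


@dataclass(frozen=True)
class TriggerWord:
    """An 8-line digital word: line k carries bit k of the marker value."""

    value: int
    lines: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.lines) != N_TRIGGER_LINES:
            raise TriggerEncodingError(
                f"trigger word needs {N_TRIGGER_LINES} lines, got {len(self.lines)}"
            )


def encode_trigger(value: int) -> TriggerWord:
    """Decompose a marker value in [0, 255] onto the 8 output lines."""
    if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
        raise TriggerEncodingError(f"trigger value must be an integer, got {value!r}")
    if not 0 <= value <= 255:
        raise TriggerEncodingError(f"trigger value {value} outside [0, 255]")
    lines = tuple(bool((int(value) >> k) & 1) for k in range(N_TRIGGER_LINES))
    return TriggerWord(int(value), lines)


def decode_trigger(lines: Sequence[bool]) -> int:
    """Inverse of :func:`encode_trigger`: read the marker value off the lines."""
    if isinstance(lines, TriggerWord):
        lines = lines.lines
    if len(lines) != N_TRIGGER_LINES:
        raise TriggerEncodingError(
            f"expected {N_TRIGGER_LINES} line states, got {len(lines)}"
        )
    return sum((1 << k) for k, state in enumerate(lines) if state)


# ---------------------------------------------------------------------------
# event log


#: Event kinds an execution run can emit.
EVENT_KINDS = ("trigger_onset", "sound_onset", "sound_offset", "stopped")


@dataclass(frozen=True)
class EventRecord:
    time_ms: float
    kind: str
    entry: int
    trigger_value: int


@dataclass
class EventLog:
    """Timestamped record of one execution run.

    Each completed entry contributes exactly one ``trigger_onset`` and one
    ``sound_onset`` (plus a ``sound_offset``); a run cut short ends with a
    single ``stopped`` record.  ``error`` is set when a backend failure, not
    a stop request, ended the run.
    """

    records: list[EventRecord] = field(default_factory=list)
    completed: bool = True
    error: str | None = None

    def times(self, kind: str) -> np.ndarray:
        """Timestamps (ms) of all records of one kind, in log order."""
        if kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {kind!r}")
        return np.array([r.time_ms for r in self.records if r.kind == kind])

    def n_completed_entries(self) -> int:
        return sum(1 for r in self.records if r.kind == "sound_onset")

    def write_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="") as fh:
            self._write(fh)

    def _write(self, fh: io.TextIOBase) -> None:
        writer = csv.writer(fh)
        writer.writerow(["time_ms", "kind", "entry", "trigger"])
        for r in self.records:
            writer.writerow([repr(float(r.time_ms)), r.kind, r.entry, r.trigger_value])

    @classmethod
    def read_csv(cls, path: str | os.PathLike) -> "EventLog":
        records = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                records.append(
                    EventRecord(
                        float(row["time_ms"]),
                        row["kind"],
                        int(row["entry"]),
                        int(row["trigger"]),
                    )
                )
        completed = not any(r.kind == "stopped" for r in records)
        return cls(records, completed=completed)


# ---------------------------------------------------------------------------
# backends


@dataclass
class NoiseModel:
    """Timing behavior of a simulated output chain.

    ``audio_latency_ms`` and ``trigger_latency_ms`` are constant offsets
    added to every sound/trigger onset; ``jitter_sd_ms`` is the SD of
    zero-mean Gaussian noise added per sound onset (trial-to-trial jitter).
    All draws come from a generator seeded with ``seed``, so a run is fully
    reproducible.
    """

    audio_latency_ms: float = 0.0
    jitter_sd_ms: float = 0.0
    trigger_latency_ms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sd_ms < 0:
            raise ValueError(f"jitter SD must be >= 0, got {self.jitter_sd_ms}")

    @property
    def is_null(self) -> bool:
        return (
            self.audio_latency_ms == 0
            and self.jitter_sd_ms == 0
            and self.trigger_latency_ms == 0
        )


class Backend(ABC):
    """Contract between the scheduling engine and an output device.

    A live implementation would submit audio buffers to a sound card and set
    physical output lines; the engine only requires that each call report the
    actual onset time it achieved (or its best estimate), in protocol
    milliseconds.  Implementations must document their latency behavior.
    """

    @abstractmethod
    def start_sound(self, event: ScheduledEvent) -> float:
        """Start the event's stimulus; return the actual sound-onset time (ms)."""

    @abstractmethod
    def assert_trigger(self, word: TriggerWord, at_ms: float) -> float:
        """Assert a trigger word at ``at_ms``; return the actual onset time (ms)."""

    @abstractmethod
    def now_ms(self) -> float:
        """Current time on the backend's clock, in protocol milliseconds."""


class SimulatedBackend(Backend):
    """Deterministic reference backend.

    Applies a :class:`NoiseModel` to the scheduled times instead of doing
    I/O: trigger onsets are shifted by the constant trigger latency, sound
    onsets by the constant audio latency plus one seeded Gaussian jitter draw
    per sound.  With a null noise model, reported onsets equal scheduled
    onsets exactly.
    """

    def __init__(self, noise: NoiseModel | None = None):
        self.noise = noise if noise is not None else NoiseModel()
        self._rng = np.random.default_rng(self.noise.seed)
        self._clock_ms = 0.0

    def start_sound(self, event: ScheduledEvent) -> float:
        onset = event.onset_ms + self.noise.audio_latency_ms
        if self.noise.jitter_sd_ms > 0:
            onset += self._rng.normal(0.0, self.noise.jitter_sd_ms)
        self._clock_ms = max(self._clock_ms, event.onset_ms)
        return onset

    def assert_trigger(self, word: TriggerWord, at_ms: float) -> float:
        self._clock_ms = max(self._clock_ms, at_ms)
        return at_ms + self.noise.trigger_latency_ms

    def now_ms(self) -> float:
        return self._clock_ms


# ---------------------------------------------------------------------------
# execution


def run_schedule(
    schedule: Schedule,
    backend: Backend | None = None,
    stop_check: Callable[[], bool] | None = None,
    trigger_pulse_ms: float = DEFAULT_TRIGGER_PULSE_MS,
) -> EventLog:
    """Execute a schedule against a backend, logging paired events.

    For each entry the trigger word and the sound are issued for the *same*
    scheduled onset; any sound/trigger asymmetry is the backend's latency
    behavior, reported through the returned timestamps.  ``stop_check`` is
    polled at entry boundaries: when it returns true, no further entries are
    issued and a terminal ``stopped`` record is logged.  A backend failure
    mid-run returns the log accumulated so far with ``error`` set.

    ``trigger_pulse_ms`` documents how long the asserted word is held before
    the lines reset to 0; it does not appear in the log (the loopback
    renderer consumes it) but is validated here.
    """
    if backend is None:
        backend = SimulatedBackend()
    if trigger_pulse_ms <= 0:
        raise ValueError(f"trigger pulse width must be > 0, got {trigger_pulse_ms}")
    log = EventLog()
    for event in schedule.events:
        if stop_check is not None and stop_check():
            log.records.append(
                EventRecord(backend.now_ms(), "stopped", event.index, 0)
            )
            log.completed = False
            return log
        word = encode_trigger(event.trigger_value)
        try:
            trig_t = float(backend.assert_trigger(word, event.onset_ms))
            sound_t = float(backend.start_sound(event))
        except BackendError as exc:
            log.records.append(
                EventRecord(backend.now_ms(), "stopped", event.index, 0)
            )
            log.completed = False
            log.error = str(exc)
            return log
        log.records.append(
            EventRecord(trig_t, "trigger_onset", event.index, event.trigger_value)
        )
        log.records.append(
            EventRecord(sound_t, "sound_onset", event.index, event.trigger_value)
        )
        log.records.append(
            EventRecord(
                sound_t + event.duration_ms,
                "sound_offset",
                event.index,
                event.trigger_value,
            )
        )
    return log


def progress_level(completed: int, total: int, n_levels: int = DEFAULT_PROGRESS_LEVELS) -> int:
    """Map run progress onto a discrete indicator (e.g. a 5-LED bar).

    Returns ``min(n_levels - 1, floor(n_levels * completed / total))``;
    monotone non-decreasing in ``completed``, level 0 at the start and the
    top level exactly at completion.
    """
    if total < 1:
        raise ValueError(f"total must be >= 1, got {total}")
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    if not 0 <= completed <= total:
        raise ValueError(f"completed {completed} outside [0, {total}]")
    return min(n_levels - 1, (n_levels * completed) // total)
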