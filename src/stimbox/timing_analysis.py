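"""Loopback latency/jitter measurement.

The benchmark for a stimulation system feeds its audio output and its trigger
lines directly (plain cable, no processing) into the two channels of one
recorder, so both share a clock.  Analysis then:

1. detects onsets on each channel by threshold crossing (first sample whose
   absolute amplitude exceeds the threshold, with a refractory re-arm rule so
   a tone's internal zero crossings do not retrigger),
2. pairs each trigger onset with the nearest sound onset within a window,
3. summarizes the signed per-pair latencies — *latency* is the mean of
   (sound onset − trigger onset), positive when the sound lags its trigger,
   and *jitter* is the sample standard deviation of that distribution.

Onset time is the index of the first supra-threshold sample converted to ms
(0-based, no sub-sample interpolation); quantization is one sample period,
about 0.023 ms at 44.1 kHz.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from stimbox.stimulus_io import load_stimulus

#: Detection threshold as a fraction of the channel's peak absolute amplitude.
DEFAULT_THRESHOLD_FRACTION = 0.1

#: Sustained sub-threshold time required before the detector re-arms.
DEFAULT_REFRACTORY_MS = 50.0

#: Half-width of the trigger-to-sound pairing window.
DEFAULT_MAX_LAG_MS = 100.0


@dataclass
class LoopbackRecording:
    """A two-channel capture: audio on one channel, trigger line on the other."""

    audio_channel: np.ndarray
    trigger_channel: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.audio_channel = np.asarray(self.audio_channel, dtype=np.float64)
        self.trigger_channel = np.asarray(self.trigger_channel, dtype=np.float64)
        if self.audio_channel.shape != self.trigger_channel.shape:
            raise ValueError(
                f"channel lengths differ: {self.audio_channel.shape} vs "
                f"{self.trigger_channel.shape}"
            )
        if self.sample_rate_hz <= 0:
            raise ValueError(f"sample rate must be > 0, got {self.sample_rate_hz}")

    @property
    def n_samples(self) -> int:
        return self.audio_channel.shape[0]

    @classmethod
    def from_wav(
        cls,
        path: str | os.PathLike,
        audio_channel: int = 0,
        trigger_channel: int = 1,
    ) -> "LoopbackRecording":
        """Load a 2-channel WAV capture (channel roles overridable)."""
        stim = load_stimulus(path)
        if stim.n_channels < 2:
            raise ValueError(f"{path}: loopback recording needs 2 channels")
        return cls(
            stim.samples[:, audio_channel],
            stim.samples[:, trigger_channel],
            stim.sample_rate_hz,
        )


@dataclass
class OnsetList:
    """Strictly increasing 0-based sample indices of detected onsets."""

    onsets: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        if self.onsets.size > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onset indices must be strictly increasing")

    def __len__(self) -> int:
        return self.onsets.size

    def times_ms(self, sample_rate_hz: float) -> np.ndarray:
        return self.onsets * 1000.0 / sample_rate_hz


@dataclass
class PairResult:
    """Trigger/sound onset pairing: matched sample-index pairs plus leftovers."""

    pairs: list[tuple[int, int]]  # (trigger sample index, sound sample index)
    unmatched_triggers: int
    unmatched_sounds: int


@dataclass
class LatencyResult:
    """Latency distribution summary of one loopback recording.

    Latencies are signed (positive = sound after trigger) in milliseconds.
    ``sd_ms`` — the jitter — is the sample standard deviation (n−1
    denominator).  With no pairs the summary statistics are NaN, never
    fabricated; with a single pair the SD is NaN.
    """

    latencies_ms: np.ndarray
    n_pairs: int
    mean_ms: float
    sd_ms: float
    min_ms: float
    max_ms: float
    unmatched_triggers: int = 0
    unmatched_sounds: int = 0

    def report(self) -> str:
        """Key/value text report."""
        lines = [
            f"n_pairs: {self.n_pairs}",
            f"mean_latency_ms: {self.mean_ms:.4f}",
            f"jitter_sd_ms: {self.sd_ms:.4f}",
            f"min_latency_ms: {self.min_ms:.4f}",
            f"max_latency_ms: {self.max_ms:.4f}",
            f"unmatched_triggers: {self.unmatched_triggers}",
            f"unmatched_sounds: {self.unmatched_sounds}",
        ]
        return "\n".join(lines)


@dataclass
class AnalysisParams:
    """Tunable parameters of the end-to-end analysis."""

    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
    refractory_ms: float = DEFAULT_REFRACTORY_MS
    max_lag_ms: float = DEFAULT_MAX_LAG_MS
    audio_channel: int = 0
    trigger_channel: int = 1


def detect_onsets(
    channel: Sequence[float] | np.ndarray,
    sample_rate_hz: float,
    threshold: float,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
) -> OnsetList:
    """Threshold onset detector with a refractory re-arm rule.

    Reports the first index whose absolute amplitude exceeds ``threshold``,
    then stays disarmed until the signal has remained at or below the
    threshold for at least ``refractory_ms``.  Detection rectifies the
    signal (sine polarity at onset is arbitrary).  On a noiseless signal
    with ``threshold=0`` this reduces to "the moment where the signal is
    nonzero".  An empty signal yields an empty list.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    if refractory_ms < 0:
        raise ValueError(f"refractory must be >= 0, got {refractory_ms}")
    x = np.abs(np.asarray(channel, dtype=np.float64))
    if x.size == 0:
        return OnsetList(np.empty(0, dtype=np.int64))
    above = x > threshold
    refractory_n = int(round(refractory_ms * sample_rate_hz / 1000.0))

    # Walk runs of the boolean mask rather than samples: the number of
    # transitions is tiny compared to the signal length.
    change = np.flatnonzero(np.diff(above))
    run_starts = np.concatenate(([0], change + 1))
    run_ends = np.concatenate((change + 1, [above.size]))

    onsets: list[int] = []
    armed = True
    for start, end in zip(run_starts, run_ends):
        if above[start]:
            if armed:
                onsets.append(int(start))
                armed = False
        else:
            if end - start >= refractory_n:
                armed = True
    return OnsetList(np.array(onsets, dtype=np.int64))


def detect_onsets_bruteforce(
    channel: Sequence[float] | np.ndarray,
    sample_rate_hz: float,
    threshold: float,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
) -> OnsetList:
    """Sample-by-sample O(N) reference detector (testing oracle).

    Implements the same contract as :func:`detect_onsets` as a literal state
    machine over individual samples; kept simple and slow on purpose.
    """
    x = np.abs(np.asarray(channel, dtype=np.float64))
    refractory_n = int(round(refractory_ms * sample_rate_hz / 1000.0))
    onsets: list[int] = []
    armed = True
    quiet = 0
    for i in range(x.size):
        if x[i] > threshold:
            if armed:
                onsets.append(i)
                armed = False
            quiet = 0
        else:
            quiet += 1
            if quiet >= refractory_n:
                armed = True
    return OnsetList(np.array(onsets, dtype=np.int64))


def pair_onsets(
    trigger_onsets: OnsetList,
    sound_onsets: OnsetList,
    sample_rate_hz: float,
    max_lag_ms: float = DEFAULT_MAX_LAG_MS,
) -> PairResult:
    """Pair each trigger with the nearest sound onset within ±max_lag_ms.

    Greedy in time order, one-to-one: triggers are visited in order and each
    claims the nearest still-unclaimed sound within the window.  Events left
    over on either side are counted, never silently dropped.
    """
    if max_lag_ms <= 0:
        raise ValueError(f"max_lag_ms must be > 0, got {max_lag_ms}")
    window = max_lag_ms * sample_rate_hz / 1000.0
    trig = trigger_onsets.onsets
    sound = sound_onsets.onsets
    taken = np.zeros(sound.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    lo = 0
    for t in trig:
        # advance past sounds that fell out of every future window
        while lo < sound.size and (taken[lo] or sound[lo] < t - window):
            lo += 1
        best = -1
        best_dist = window + 1
        j = lo
        while j < sound.size and sound[j] <= t + window:
            if not taken[j]:
                dist = abs(int(sound[j]) - int(t))
                if dist < best_dist:
                    best_dist = dist
                    best = j
            j += 1
        if best >= 0 and best_dist <= window:
            taken[best] = True
            pairs.append((int(t), int(sound[best])))
    return PairResult(
        pairs=pairs,
        unmatched_triggers=trig.size - len(pairs),
        unmatched_sounds=sound.size - len(pairs),
    )


def summarize_latencies(
    pairs: PairResult | Sequence[tuple[int, int]],
    sample_rate_hz: float,
) -> LatencyResult:
    """Summarize signed latencies (sound − trigger) of matched pairs.

    The jitter (``sd_ms``) uses the n−1 denominator.  Zero pairs gives NaN
    mean/SD/min/max; one pair gives NaN SD.
    """
    if isinstance(pairs, PairResult):
        pair_list = pairs.pairs
        unmatched_t = pairs.unmatched_triggers
        unmatched_s = pairs.unmatched_sounds
    else:
        pair_list = list(pairs)
        unmatched_t = unmatched_s = 0
    lat = np.array(
        [(s - t) * 1000.0 / sample_rate_hz for t, s in pair_list], dtype=np.float64
    )
    n = lat.size
    return LatencyResult(
        latencies_ms=lat,
        n_pairs=n,
        mean_ms=float(np.mean(lat)) if n else math.nan,
        sd_ms=float(np.std(lat, ddof=1)) if n > 1 else math.nan,
        min_ms=float(np.min(lat)) if n else math.nan,
        max_ms=float(np.max(lat)) if n else math.nan,
        unmatched_triggers=unmatched_t,
        unmatched_sounds=unmatched_s,
    )


def analyze_recording(
    rec: LoopbackRecording,
    params: AnalysisParams | None = None,
) -> LatencyResult:
    """Full loopback analysis: detect onsets on both channels, pair, summarize.

    The detection threshold for each channel is ``threshold_fraction`` times
    that channel's peak absolute amplitude, so audio and trigger levels need
    not match.  Deterministic for fixed input and parameters.
    """
    if params is None:
        params = AnalysisParams()
    results = {}
    for name, channel in (
        ("audio", rec.audio_channel),
        ("trigger", rec.trigger_channel),
    ):
        peak = float(np.max(np.abs(channel))) if channel.size else 0.0
        results[name] = detect_onsets(
            channel,
            rec.sample_rate_hz,
            threshold=params.threshold_fraction * peak,
            refractory_ms=params.refractory_ms,
        )
    paired = pair_onsets(
        results["trigger"],
        results["audio"],
        rec.sample_rate_hz,
        max_lag_ms=params.max_lag_ms,
    )
    return summarize_latencies(paired, rec.sample_rate_hz)


def write_latency_table(result: LatencyResult, path: str | os.PathLike) -> None:
    """Write the per-pair latency table as comma-separated text."""
    with open(path, "w") as fh:
        fh.write("pair,latency_ms\n")
        for i, lat in enumerate(result.latencies_ms):
            fh.write(f"{i},{float(lat)!r}\n")


def plot_latencies(result: LatencyResult, path: str | os.PathLike) -> None:
    """Save a violin-plus-points plot of the latency distribution."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 5))
    if result.n_pairs:
        if result.n_pairs > 1 and np.ptp(result.latencies_ms) > 0:
            ax.violinplot(result.latencies_ms, positions=[0], showmeans=True)
        jitter_x = np.linspace(-0.08, 0.08, result.n_pairs)
        ax.plot(jitter_x, result.latencies_ms, ".", ms=3, alpha=0.4, color="k")
    ax.set_ylabel("latency (ms)")
    ax.set_xticks([])
    title = (
        f"mean {result.mean_ms:.3f} ms, jitter (SD) {result.sd_ms:.3f} ms, "
        f"n = {result.n_pairs}"
    )
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
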