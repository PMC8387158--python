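# Methods

## Protocol model

A protocol is an ordered table of presentations (the *playframe*): stimulus
WAV file, trigger marker, inter-stimulus interval. The ISI convention is
offset-to-onset — the silent gap in milliseconds from the end of one sound to
the beginning of the next — so absolute onsets follow the exact recurrence

```
onset(0)   = 0
onset(i+1) = onset(i) + duration(i) + isi(i)
```

computed in plain floating-point milliseconds. Time stays real-valued
throughout the engine; conversion to sample indices happens only at the
loopback-rendering boundary, avoiding premature quantization. Integer-valued
durations and ISIs therefore produce integer-valued onsets with no drift.

Protocol stimuli are stereo PCM WAV at 44,100 Hz; validation flags missing
files, non-WAV data, wrong channel count, and wrong sample rate per entry
rather than raising, so a whole protocol can be audited in one pass. The
protocol file carries the three canonical headers `stim`, `trigger`, `isi`
(case-insensitive, remappable); CSV is the primary dialect and Excel a
convenience. ISIs are written with `repr` and read with round-trip float
parsing so write→read is the identity bit for bit.

## Trigger markers

Markers are integers in [0, 255] asserted on 8 digital output lines — the
data lines of the parallel-port input that EEG amplifiers conventionally
read. Line *k* carries bit *k* (LSB-first); any fixed bijection yields the
same 256-value space, and committing to LSB-first lets wiring follow the
software. Marker 0 is legal and means "no line asserted". The asserted word
is held for a finite pulse (default 10 ms) and then reset; EEG acquisition
needs a nonzero pulse width, and the renderer needs a concrete value.

## Execution and the simulated backend

The engine issues each entry's trigger word and sound start *for the same
scheduled onset*; any sound/trigger asymmetry is a property of the output
chain, not of the schedule. The backend contract is three calls
(`assert_trigger`, `start_sound`, `now_ms`), each returning the actual onset
it achieved, so a live implementation (sound card + physical lines) can
report measured or estimated timestamps. The shipped reference backend is
purely simulated: it applies a noise model

- `trigger_latency_ms` — constant shift of every trigger onset,
- `audio_latency_ms` — constant shift of every sound onset,
- `jitter_sd_ms` — zero-mean Gaussian added per sound onset,

with all draws from one generator seeded by `seed`, so runs are exactly
reproducible and a null model reproduces the compiled schedule bit for bit.
Stop requests are honored at entry boundaries (a run cut short ends with a
single terminal `stopped` record); a backend failure returns the log
accumulated so far with the error flagged. Progress maps onto a discrete
indicator as `min(n_levels − 1, floor(n_levels · completed / total))` with 5
levels by default, matching a 5-LED progress bar.

## Loopback measurement

The benchmark feeds the system's audio and trigger outputs through a plain
cable into the two channels of one recorder, giving both a shared clock.
Analysis is: detect onsets per channel → pair → summarize.

**Onset detection.** The idealized rule — the moment the signal departs from
zero — is ill-posed for real captures (noise floor) and for a sine that
re-crosses zero every half-cycle. The detector therefore (a) rectifies the
signal, since onset polarity is arbitrary; (b) uses a threshold defaulting to
0.1 × the channel's peak absolute amplitude, which reduces to the idealized
rule on noiseless signals; and (c) after a detection stays disarmed until the
signal has remained at or below threshold for a refractory window (default
50 ms, longer than a half-cycle of any plausible stimulus but shorter than
any plausible ISI). Onset time is the index of the first supra-threshold
sample, 0-based, converted as `index · 1000 / rate` with no sub-sample
interpolation; quantization is one sample period, ~0.023 ms at 44.1 kHz,
below any effect of practical interest. A brute-force sample-by-sample
state machine with the identical contract is kept as an independent oracle
and cross-checked in the tests.

**Pairing.** Each trigger onset, in time order, greedily claims the nearest
still-unclaimed sound onset within ±100 ms (default). The window is an order
of magnitude above the worst latencies reported for common stimulation
setups while rejecting cross-event pairing at typical ISIs. Unmatched events
on either side are counted, never silently dropped.

**Summary.** Latency is signed, `sound onset − trigger onset` (positive =
sound lags its trigger); swapping channels negates every latency. Jitter is
the sample standard deviation (n − 1 denominator). Zero pairs yields NaN
statistics rather than fabricated values; one pair yields NaN SD.

## Synthetic loopback rendering

The renderer turns an event log into the two-channel signal the cable would
deliver: a rectangular pulse (default 10 ms wide, amplitude 1.0) at each
trigger onset and a copy of the test tone at each sound onset, on one shared
clock, plus optional seeded Gaussian amplitude noise and 500 ms of tail
silence. Overlapping events sum and clip to [−1, 1]. Only pulse *presence*
is rendered — the loopback method measures timing, not marker value, which
is covered by the exhaustive encode/decode check.

One deliberate alignment choice: the tone is placed so that its first
*observable* (nonzero) sample sits at the onset index. A phase-0 sine starts
at an exact zero crossing that no threshold detector can see; leaving the
leading zero sample in place would shift every measured sound onset late by
one sample and bias the recovered latency by a constant ~0.023 ms. With the
alignment, a null noise model yields latencies of exactly 0 samples.

What the synthetic path does **not** emulate: analog rise times, cable
capacitance, anti-aliasing filters, clock drift between player and recorder,
or acoustic propagation. Passing tests therefore demonstrate the protocol,
engine, and measurement chain are correct and unbiased at the sample level —
not that any particular hardware meets a latency budget; that requires the
same analysis on a physical loopback recording.

## Calibration protocol

The reference benchmark signal: a 1000 Hz, 200 ms stereo tone at 44,100 Hz
(8820 samples per channel), hard onset and offset (no ramps — a ramp would
bias threshold detection), amplitude 0.9, repeated 1000 times with trigger
value 255. The repetition ISI defaults to 500 ms, a value that separates
events safely (well above tone duration plus pairing window) while keeping a
full synthetic run to ~12 minutes of rendered audio; a (low, high) range
substitutes seeded uniform moving ISIs. Synthesized tones start at phase 0
(first sample exactly 0, second positive) and are written as 16-bit PCM, so
a save/load roundtrip is the identity within one quantization step (2⁻¹⁵).

## Numerical and scale choices

- Sampling-theory test bounds: at n = 1000 injected (L = 5 ms, σ = 1 ms) must
  be recovered with mean within 3σ/√n ≈ 0.095 ms and SD inside [0.93, 1.07]
  (the central 99% band of the sample-SD distribution); the acceptance suite
  runs this across 10 seeds at the full 1000-event scale (~40 s).
- Unit tests use 5–100-event protocols; statistical properties are checked at
  1000 events, degenerate and boundary behavior at tiny n.
- Amplitude-noise robustness: capture noise with SD ≤ 0.1 × threshold leaves
  every detected onset index unchanged (crossing a 10-SD margin is
  negligible), verified on tone-burst fixtures.
- Ties in pairing (two sounds equidistant from a trigger) resolve to the
  earlier sound; detection on an empty signal returns an empty onset list.

## Known limitations

- The live audio/GPIO path is a documented contract, not shipped code; all
  shipped execution is simulated.
- The trigger channel is analyzed with the same threshold rule as audio;
  analog pulse shape (rise time) is not modeled.
- No stimulus preprocessing (resampling, filtering, loudness normalization)
  and no response collection.
- Protocol intelligence (randomization constraints, block balancing) is out
  of scope beyond seeded shuffling; playframes are expected to be generated
  by study-specific code.
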