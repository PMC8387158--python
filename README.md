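# stimbox

Auditory stimulation protocols with EEG trigger synchronization — a
hardware-agnostic toolkit for building, simulating, and benchmarking
auditory stimulation systems.

Time-locked EEG analyses (evoked potentials, phase coherence, reaction
times) are only as accurate as the stimulation system's timing: the delay
between a sound's physical onset and the trigger marker the amplifier
records (**latency**), and that delay's trial-to-trial variability
(**jitter**, the standard deviation of the latency distribution), vary
widely across computers, operating systems, drivers, and presentation
software. `stimbox` implements the full workflow for specifying a protocol,
executing it, and measuring a system's timing with a loopback test — all
testable on a desk, without lab hardware.

## What it provides

- **Playframe protocol format** — an experiment playlist as a plain CSV
  table (columns `stim`, `trigger`, `isi`): one row per stimulus
  presentation, giving the stereo WAV file name, the integer trigger marker
  in [0, 255] asserted at sound onset, and the inter-stimulus interval in ms
  (measured from the *end* of one sound to the *start* of the next).
  Reading, writing, validation against a `stim/` folder (stereo, 44,100 Hz),
  and seeded generation with fixed or uniformly drawn ("moving") ISIs.
- **Scheduler and execution engine** — compiles a playframe into absolute
  onset times, `onset(i+1) = onset(i) + duration(i) + isi(i)`, and runs it
  against a pluggable output backend, logging paired trigger/sound onset
  events with stop-at-any-time interruption and discrete progress reporting.
  The shipped backend is a deterministic simulation driven by a seeded noise
  model (constant audio/trigger latencies plus Gaussian onset jitter).
- **Trigger encoding** — markers are placed on 8 digital output lines (the
  parallel-port data lines EEG amplifiers read), line *k* carrying bit *k*,
  giving the full 2⁸ = 256 distinct marker values.
- **Loopback timing analysis** — the standard benchmark: the system's audio
  and trigger outputs are fed directly into the two channels of one
  recorder, onsets are detected on each channel by threshold crossing (with
  a refractory re-arm rule so a tone's internal zero crossings don't
  retrigger), triggers are paired with the nearest sound onset, and the
  latency distribution is summarized (mean, SD = jitter, min, max, n).
- **Synthetic loopback rendering** — renders an execution log into the
  two-channel recording a physical loopback cable would produce, with known
  injected latency and jitter, so the whole measurement chain is validated
  end to end: inject (L, σ), render, analyze, recover (L, σ).

## Worked example

The calibration protocol is the reference benchmark: a 1000 Hz, 200 ms
stereo tone (44,100 Hz) repeated 1000 times, each presentation marked with
trigger value 255. Below it is executed on the simulated backend with an
injected constant audio latency of 5 ms and 1 ms Gaussian onset jitter, then
measured back from the rendered loopback recording:

```python
from stimbox import NoiseModel, analyze_recording
from stimbox.synthetic_loopback import render_calibration

noise = NoiseModel(audio_latency_ms=5.0, jitter_sd_ms=1.0, seed=0)
rec = render_calibration(n_repeats=1000, noise=noise)
result = analyze_recording(rec)
print(result.report())
```

```
n_pairs: 1000
mean_latency_ms: 4.9521
jitter_sd_ms: 0.9772
min_latency_ms: 1.1111
max_latency_ms: 8.0726
unmatched_triggers: 0
unmatched_sounds: 0
```

All 1000 trigger/sound pairs were matched; the recovered mean latency
(4.95 ms) and jitter (0.98 ms) agree with the injected 5 ms and 1 ms within
the sampling error expected at n = 1000 (3σ/√n ≈ 0.095 ms for the mean).
With a null noise model every latency is exactly 0 samples.

## Command line

One subcommand per workflow stage:

```bash
stimbox generate playframe.csv -s beep.wav -t 255 -s word.wav -t 12 --isi 500
stimbox validate playframe.csv --stim-dir stim      # exit 0 iff protocol valid
stimbox simulate playframe.csv --out log.csv --jitter 1 --seed 7
stimbox calibrate --n 1000 --audio-latency 5 --jitter 1 --out-dir run/
stimbox analyze run/loopback.wav --table latencies.csv --plot latencies.png
```

`calibrate` writes a synthetic loopback WAV plus a sidecar listing the
injected parameters; `analyze` recovers them. Every command writes a
reproducibility sidecar (`*.meta.yaml`) with the package version, seed, and
parameters; exit codes are 0 (ok), 1 (validation failure), 2 (execution
error).

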