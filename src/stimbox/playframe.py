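"""The playframe protocol format.

A playframe is the ordered playlist that drives an auditory stimulation run:
one row per stimulus presentation, holding the stimulus WAV file name, the
integer trigger marker (0-255) asserted on the parallel-port lines at sound
onset, and the inter-stimulus interval (ISI) in milliseconds.  The ISI is
measured *offset-to-onset*: from the end of the current sound to the beginning
of the next one.

Playframes live in plain comma-separated text with a header row (columns
``stim``, ``trigger``, ``isi``); Excel files are accepted as a secondary
dialect.  The protocol file carries no filesystem knowledge: checking that
the referenced stimuli exist and have the right format is
:func:`validate_playframe`'s job, so protocols can be authored on one machine
and played on another.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from stimbox.errors import (
    ISIValueError,
    MissingColumnError,
    PlayframeError,
    StimulusNameError,
    TriggerValueError,
)

#: Canonical column headers of the protocol table, in order.
COLUMNS = ("stim", "trigger", "isi")

#: Conventional file stem for protocol tables.
CANONICAL_STEM = "playframe"

#: Required stimulus format for protocol WAV files.
STIMULUS_SAMPLE_RATE_HZ = 44_100
STIMULUS_CHANNELS = 2


@dataclass(frozen=True)
class PlayEntry:
    """One row of a playframe: a stimulus presentation.

    Parameters
    ----------
    stimulus_name
        File name of the stereo WAV stimulus, relative to the protocol's
        ``stim`` folder.
    trigger_value
        Integer marker in [0, 255] asserted on the 8 output lines at sound
        onset.  0 is legal and means "no line asserted".
    isi_ms
        Silence in milliseconds from the end of this sound to the start of
        the next.  Non-negative; sub-millisecond values are allowed.
    """

    stimulus_name: str
    trigger_value: int
    isi_ms: float

    def __post_init__(self) -> None:
        if not isinstance(self.stimulus_name, str) or not self.stimulus_name:
            raise StimulusNameError("stimulus_name must be a non-empty string")
        if isinstance(self.trigger_value, bool) or not isinstance(
            self.trigger_value, (int, np.integer)
        ):
            raise TriggerValueError(
                f"trigger value must be an integer, got {self.trigger_value!r}"
            )
        if not 0 <= self.trigger_value <= 255:
            raise TriggerValueError(
                f"trigger value {self.trigger_value} outside [0, 255]"
            )
        if not isinstance(self.isi_ms, (int, float, np.integer, np.floating)):
            raise ISIValueError(f"ISI must be numeric, got {self.isi_ms!r}")
        if not math.isfinite(float(self.isi_ms)) or float(self.isi_ms) < 0:
            raise ISIValueError(f"ISI must be finite and >= 0, got {self.isi_ms}")
        object.__setattr__(self, "trigger_value", int(self.trigger_value))
        object.__setattr__(self, "isi_ms", float(self.isi_ms))


@dataclass
class Playframe:
    """An ordered protocol playlist.

    Entry order *is* the presentation order; an empty playframe is degenerate
    but valid.
    """

    entries: list[PlayEntry] = field(default_factory=list)
    source_path: str | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, i):
        return self.entries[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Playframe):
            return NotImplemented
        return self.entries == other.entries

    def to_frame(self) -> pd.DataFrame:
        """Return the protocol as a DataFrame with the canonical columns."""
        return pd.DataFrame(
            [(e.stimulus_name, e.trigger_value, e.isi_ms) for e in self.entries],
            columns=list(COLUMNS),
        )


@dataclass
class ValidationReport:
    """Outcome of checking a playframe against a stimulus folder.

    ``issues`` is a list of ``(entry_index, code, message)`` tuples; the index
    is ``None`` for report-level problems (e.g. the stimulus folder itself is
    missing).  ``ok`` is true iff there are no issues.
    """

    issues: list[tuple[int | None, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, index: int | None, code: str, message: str) -> None:
        self.issues.append((index, code, message))

    def __str__(self) -> str:
        if self.ok:
            return "OK: playframe valid"
        lines = [f"{len(self.issues)} issue(s):"]
        for index, code, message in self.issues:
            where = "playframe" if index is None else f"entry {index}"
            lines.append(f"  {where}: [{code}] {message}")
        return "\n".join(lines)


def _resolve_columns(
    raw_columns: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    """Map canonical names to actual file headers, case-insensitively."""
    lookup: dict[str, str] = {}
    lowered: dict[str, list[str]] = {}
    for col in raw_columns:
        lowered.setdefault(str(col).strip().lower(), []).append(col)
    for canonical in COLUMNS:
        wanted = canonical
        if column_map and canonical in column_map:
            wanted = column_map[canonical]
        matches = lowered.get(wanted.strip().lower(), [])
        if len(matches) == 0:
            raise MissingColumnError(
                f"required column {wanted!r} not found; file has {list(raw_columns)!r}"
            )
        if len(matches) > 1:
            raise MissingColumnError(
                f"column {wanted!r} is ambiguous in {list(raw_columns)!r}"
            )
        lookup[canonical] = matches[0]
    return lookup


def _entry_from_row(index: int, stim, trigger, isi) -> PlayEntry:
    if stim is None or (isinstance(stim, float) and math.isnan(stim)) or str(stim) == "":
        raise StimulusNameError(f"entry {index}: empty stimulus name")
    trig_f = float(trigger)
    if math.isnan(trig_f):
        raise TriggerValueError(f"entry {index}: missing trigger value")
    if trig_f != int(trig_f):
        raise TriggerValueError(
            f"entry {index}: trigger {trigger!r} is not an integer"
        )
    trig = int(trig_f)
    if not 0 <= trig <= 255:
        raise TriggerValueError(f"entry {index}: trigger {trig} outside [0, 255]")
    isi_f = float(isi)
    if not math.isfinite(isi_f) or isi_f < 0:
        raise ISIValueError(f"entry {index}: ISI {isi!r} must be finite and >= 0")
    return PlayEntry(str(stim), trig, isi_f)


def read_playframe(
    path: str | os.PathLike,
    column_map: Mapping[str, str] | None = None,
) -> Playframe:
    """Read a protocol table from a CSV (or Excel) file.

    Parameters
    ----------
    path
        Protocol file.  ``.xls``/``.xlsx`` are read with pandas' Excel
        reader; anything else is treated as comma-separated text.
    column_map
        Optional mapping from canonical column names (``stim``, ``trigger``,
        ``isi``) to the headers actually used in the file.  Header matching
        is case-insensitive either way.

    Returns
    -------
    Playframe
        Entries in file order.  Rows are fully validated; the first bad row
        raises a specific :class:`~stimbox.errors.PlayframeError` subclass
        naming the entry index.

    Notes
    -----
    By convention the protocol file is named ``playframe.csv``; a different
    stem only triggers a warning, never an error.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"playframe file not found: {p}")
    if p.stem.lower() != CANONICAL_STEM:
        warnings.warn(
            f"protocol file stem {p.stem!r} differs from the conventional "
            f"{CANONICAL_STEM!r}",
            UserWarning,
            stacklevel=2,
        )
    try:
        if p.suffix.lower() in (".xls", ".xlsx"):
            frame = pd.read_excel(p)
        else:
            frame = pd.read_csv(p, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise PlayframeError(f"{p}: no header row") from exc
    lookup = _resolve_columns(frame.columns, column_map)
    entries = []
    for index, row in enumerate(frame.itertuples(index=False)):
        row_d = dict(zip(frame.columns, row))
        try:
            entries.append(
                _entry_from_row(
                    index,
                    row_d[lookup["stim"]],
                    row_d[lookup["trigger"]],
                    row_d[lookup["isi"]],
                )
            )
        except (ValueError, TypeError) as exc:
            # float()/int() failures on non-numeric cells
            raise TriggerValueError(f"entry {index}: {exc}") from exc
    return Playframe(entries, source_path=str(p))


def write_playframe(pf: Playframe, path: str | os.PathLike) -> None:
    """Write a playframe as comma-separated text (or Excel by extension).

    ``read_playframe(write_playframe(pf))`` reproduces ``pf`` field for
    field; an empty playframe writes the header row only.
    """
    p = Path(path)
    frame = pf.to_frame()
    if p.suffix.lower() in (".xls", ".xlsx"):
        frame.to_excel(p, index=False)
    else:
        # repr round-trips doubles exactly; pandas' default float formatting
        # can drop the last digit
        frame["isi"] = frame["isi"].map(lambda v: repr(float(v)))
        frame.to_csv(p, index=False)


def validate_playframe(pf: Playframe, stim_dir: str | os.PathLike) -> ValidationReport:
    """Check every entry's stimulus against the ``stim`` folder.

    Flags, per entry: missing file (``missing_file``), unreadable/non-WAV
    file (``not_wav``), wrong channel count (``channels``, stereo required),
    wrong sample rate (``sample_rate``, 44,100 Hz required).  A missing
    stimulus folder is a report-level issue (index ``None``), not an
    exception, so validation output is always a report.
    """
    from stimbox.stimulus_io import read_wav_header

    report = ValidationReport()
    stim_path = Path(stim_dir)
    if not stim_path.is_dir():
        report.add(None, "missing_stim_dir", f"stimulus folder not found: {stim_path}")
        return report
    for index, entry in enumerate(pf.entries):
        wav = stim_path / entry.stimulus_name
        if not wav.is_file():
            report.add(index, "missing_file", f"stimulus not found: {wav}")
            continue
        try:
            rate, channels, _ = read_wav_header(wav)
        except Exception as exc:
            report.add(index, "not_wav", f"{wav.name}: not a readable WAV ({exc})")
            continue
        if channels != STIMULUS_CHANNELS:
            report.add(
                index,
                "channels",
                f"{wav.name}: {channels} channel(s), stereo required",
            )
        if rate != STIMULUS_SAMPLE_RATE_HZ:
            report.add(
                index,
                "sample_rate",
                f"{wav.name}: {rate} Hz, {STIMULUS_SAMPLE_RATE_HZ} Hz required",
            )
    return report


def total_duration_ms(
    pf: Playframe,
    durations_ms: Sequence[float],
    include_final_isi: bool = False,
) -> float:
    """Total protocol duration given per-entry stimulus durations.

    Sums stimulus durations plus the ISIs between entries; the ISI after the
    last stimulus is included only when ``include_final_isi`` is true (useful
    when concatenating protocols).
    """
    if len(durations_ms) != len(pf):
        raise ValueError(
            f"{len(durations_ms)} durations for {len(pf)} entries"
        )
    total = float(sum(durations_ms))
    for i, entry in enumerate(pf.entries):
        if include_final_isi or i < len(pf) - 1:
            total += entry.isi_ms
    return total


def generate_playframe(
    stimulus_names: Sequence[str],
    triggers: Sequence[int],
    isi_spec: float | tuple[float, float],
    order: str = "as_given",
    seed: int = 0,
) -> Playframe:
    """Build a playframe programmatically.

    Parameters
    ----------
    stimulus_names, triggers
        Parallel sequences; each (name, trigger) pair becomes one entry.
    isi_spec
        Either a fixed ISI in ms, or a ``(low, high)`` range from which ISIs
        are drawn uniformly (the "moving ISI" design used to stress-test
        stimulation timing).
    order
        ``"as_given"`` keeps input order; ``"shuffled"`` applies a seeded
        permutation to the (name, trigger) pairs.
    seed
        Seeds both the ISI draws and the shuffle; identical seeds give
        identical playframes.
    """
    if len(stimulus_names) != len(triggers):
        raise ValueError(
            f"{len(stimulus_names)} names but {len(triggers)} triggers"
        )
    if order not in ("as_given", "shuffled"):
        raise ValueError(f"order must be 'as_given' or 'shuffled', got {order!r}")
    n = len(stimulus_names)
    rng = np.random.default_rng(seed)
    if isinstance(isi_spec, (tuple, list)):
        low, high = float(isi_spec[0]), float(isi_spec[1])
        if low < 0 or high < low:
            raise ISIValueError(f"invalid ISI range ({low}, {high})")
        isis = rng.uniform(low, high, size=n)
    else:
        fixed = float(isi_spec)
        if fixed < 0 or not math.isfinite(fixed):
            raise ISIValueError(f"ISI must be finite and >= 0, got {fixed}")
        isis = np.full(n, fixed)
    pairs = list(zip(stimulus_names, triggers))
    if order == "shuffled":
        perm = rng.permutation(n)
        pairs = [pairs[i] for i in perm]
    entries = [
        PlayEntry(name, trig, isi) for (name, trig), isi in zip(pairs, isis)
    ]
    return Playframe(entries)
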