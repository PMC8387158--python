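"""Exception hierarchy.

Each malformed-input condition raises a distinct class so callers (and the
command line) can tell a format problem from a range problem without parsing
messages.
"""


class StimboxError(Exception):
    """Base class for all package errors."""


class PlayframeError(StimboxError):
    """Base class for playframe format errors."""


class MissingColumnError(PlayframeError):
    """A required protocol column is absent or matched more than once."""


class TriggerValueError(PlayframeError):
    """Trigger marker is not an integer in [0, 255]."""


class ISIValueError(PlayframeError):
    """Inter-stimulus interval is negative or not a finite number."""


class StimulusNameError(PlayframeError):
    """Stimulus file name is empty."""


class StimulusError(StimboxError):
    """WAV stimulus could not be read, written, or synthesized."""


class ScheduleError(StimboxError):
    """Schedule compilation received inconsistent inputs."""


class TriggerEncodingError(StimboxError):
    """Trigger word encode/decode received out-of-range input."""


class BackendError(StimboxError):
    """An output backend failed during execution."""
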