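"""Exception hierarchy for semgkit."""


class SemgKitError(Exception):
    """Base class for all semgkit errors."""


class FormatError(SemgKitError):
    """A file could not be parsed as a multichannel recording."""


class ConfigError(SemgKitError):
    """A configuration object violates its invariants."""


class NoOnsetError(SemgKitError):
    """No frame run exceeded the adaptive energy threshold.

    Distinct from other errors so callers can treat "no action in this
    trial" as an expected, recoverable outcome.
    """


class SegmentError(SemgKitError):
    """The recording is too short to hold the requested segment."""


class DegenerateDataError(SemgKitError):
    """Input data is degenerate for the requested operation
    (e.g. zero total channel energy, single-class labels)."""
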