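"""Exception hierarchy for the tracker.

Grouped so the command-line layer can map error families to distinct
exit codes: input/format problems, sequence-level problems, and
internal contract violations.
"""


class OverlapTrackError(Exception):
    """Base class for all package errors."""


class MaskFormatError(OverlapTrackError):
    """An image is not a valid single-channel non-negative label mask."""


class MaskIOError(OverlapTrackError):
    """A mask file could not be read or written."""


class LabelRangeError(OverlapTrackError):
    """A label exceeds the range of the requested output container."""


class SequenceError(OverlapTrackError):
    """A mask sequence is too short or internally inconsistent."""


class ContractViolationError(OverlapTrackError):
    """An operation was called with arguments outside its contract."""


class ConsistencyError(OverlapTrackError):
    """Cross-referenced tracking structures disagree with each other."""
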