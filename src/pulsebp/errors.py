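"""Exception hierarchy for the pulse-wave pipeline."""


class PulseBPError(Exception):
    """Base class for all package errors."""


class MetadataError(PulseBPError):
    """Sidecar metadata missing or invalid (e.g. absent or non-positive fs)."""


class FormatError(PulseBPError):
    """Signal file malformed: bad columns, length mismatch, non-finite samples."""


class ParameterError(PulseBPError):
    """A processing parameter is incompatible with the input (e.g. fs too low)."""


class DegenerateBeatError(PulseBPError):
    """A beat violates the preconditions of a feature computation."""


class FiducialError(PulseBPError):
    """A landmark could not be located; the beat is unusable."""


class DegenerateFeatureError(PulseBPError):
    """A calibration feature is constant over the training rows."""


class RecordRejectedError(PulseBPError):
    """Too few accepted beats to form a record-level feature vector."""
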