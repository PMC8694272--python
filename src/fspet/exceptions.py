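"""Exception hierarchy for fspet."""


class FspetError(Exception):
    """Base class for all package errors."""


class FormatError(FspetError):
    """A file could not be read in the stated format."""


class InconsistencyError(FspetError):
    """Slices of a series disagree (e.g. mixed dimensions in a DICOM dir)."""


class DataError(FspetError):
    """Input data violates a numeric contract (NaN/Inf, non-binary mask...)."""


class GenerationError(FspetError):
    """Phantom parameters produced a degenerate (e.g. empty) object."""


class ConfigurationError(FspetError):
    """Incompatible configuration (shape mismatches between stages...)."""


class StateError(FspetError):
    """An operation was called in an invalid model state (e.g. unfrozen CAE)."""


class EmptyMaskError(FspetError):
    """A metric that needs a nonempty mask received an empty one."""
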