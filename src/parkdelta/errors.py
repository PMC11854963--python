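"""Exception types shared across the pipeline."""


class ParkDeltaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ParkDeltaError):
    """A file, column map or threshold configuration is invalid."""


class EmptyStreamError(ParkDeltaError):
    """An input file or stream contains no usable readings."""


class InsufficientDataError(ParkDeltaError):
    """Too few observations for the requested estimate or fit."""
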