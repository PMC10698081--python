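"""Exception hierarchy for the respcine pipeline."""


class RespcineError(Exception):
    """Base class for all package-specific errors."""


class InvalidPhysiologyError(RespcineError, ValueError):
    """A physiological parameter combination is impossible (e.g. EDV <= ESV)."""


class GeometryError(RespcineError, ValueError):
    """Phantom geometry does not fit the field of view."""


class DegenerateSignalError(RespcineError, ValueError):
    """A surrogate signal carries no usable respiratory information."""


class InsufficientDataError(RespcineError, ValueError):
    """Too few frames, points or cycles for the requested computation."""


class MetadataError(RespcineError, ValueError):
    """Frame metadata is missing, inconsistent or implausible."""


class ConfigurationError(RespcineError, ValueError):
    """A run or phantom configuration is invalid."""
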