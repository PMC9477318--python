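"""Exception hierarchy used across the package."""


class WhiskmapError(Exception):
    """Base class for package errors."""


class ParameterError(WhiskmapError, ValueError):
    """A configuration or call parameter is invalid."""


class InputError(WhiskmapError, ValueError):
    """An input file or data array is malformed."""


class GeometryError(WhiskmapError, ValueError):
    """Degenerate geometry (coincident points, zero-length directions, ...)."""


class DomainError(WhiskmapError, ValueError):
    """A value lies outside the mathematical domain of an operation."""


class StateError(WhiskmapError, RuntimeError):
    """An operation was called on an object in an unusable state."""


class InsufficientDataError(WhiskmapError, RuntimeError):
    """Not enough records to run a statistical procedure."""


class VersionError(WhiskmapError, ValueError):
    """A persisted file carries an unsupported schema version."""
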