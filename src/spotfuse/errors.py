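"""Exception hierarchy shared across the package.

Three failure classes are distinguished so callers (and the CLI) can map
them to exit codes: malformed files, semantically invalid data, and bad
user-supplied parameters.
"""


class SpotfuseError(Exception):
    """Base class for all package errors."""


class FormatError(SpotfuseError):
    """A file does not conform to its expected on-disk format."""


class ValidationError(SpotfuseError):
    """Structurally parseable data violates a domain invariant."""


class ParameterError(SpotfuseError):
    """A user-supplied parameter is out of its admissible range."""


class ZeroVarianceError(ValidationError):
    """A statistic requiring variance was handed a constant vector."""
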