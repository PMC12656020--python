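"""Exception hierarchy.

All package errors derive from :class:`FixkitError` so callers (and the CLI)
can map them to exit codes without matching on builtins.
"""


class FixkitError(Exception):
    """Base class for all fixkit errors."""


class FormatError(FixkitError, ValueError):
    """A file or config does not follow the expected schema."""


class StreamValidationError(FixkitError, ValueError):
    """A landmark stream violates a structural invariant."""


class CapabilityError(FixkitError, RuntimeError):
    """A requested backend or optional capability is unavailable."""


class DegenerateFrameError(FixkitError, ValueError):
    """A frame's geometry does not admit the requested computation."""
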