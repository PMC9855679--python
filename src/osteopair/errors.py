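"""Exception hierarchy.

All errors raised by osteopair derive from :class:`OsteopairError` so callers
can catch the package's failures with one clause.  Validation problems are
also ``ValueError`` subclasses, format problems also ``IOError`` subclasses,
so generic handling keeps working.
"""


class OsteopairError(Exception):
    """Base class for all osteopair errors."""


class MeshFormatError(OsteopairError, IOError):
    """A mesh file is unreadable, truncated, or in an unsupported dialect."""


class ValidationError(OsteopairError, ValueError):
    """Geometry or data violates a structural invariant."""


class SchemaError(OsteopairError, ValueError):
    """A structured input file is missing required keys or has bad types."""


class ProcessingError(OsteopairError, RuntimeError):
    """An operation produced a pathological result (e.g. zero visible faces)."""
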