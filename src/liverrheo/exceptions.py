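"""Exception hierarchy.

All errors raised by the package derive from :class:`LiverRheoError` so that
callers can catch package failures with a single except clause.  Most are also
``ValueError`` subclasses, which keeps them idiomatic for bad-input handling.
"""


class LiverRheoError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LiverRheoError, ValueError):
    """Unknown condition label, preset, or configuration key."""


class ValidationError(LiverRheoError, ValueError):
    """An input value violates a documented invariant."""


class FormatError(LiverRheoError, ValueError):
    """A file does not conform to the trace/sweep schema."""


class StructureError(LiverRheoError, ValueError):
    """A trace cannot be segmented into measurement plateaus."""


class InsufficientDataError(LiverRheoError, ValueError):
    """Fewer samples than the operation fundamentally requires."""


class IdentifiabilityError(LiverRheoError, ValueError):
    """The data cannot constrain a model parameter (e.g. single axial level)."""


class FitConvergenceError(LiverRheoError, RuntimeError):
    """The nonlinear fit failed to converge from every start point."""
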