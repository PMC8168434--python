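"""Exception types shared across the pipeline."""


class PerfutexError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PerfutexError, ValueError):
    """An argument violates a documented precondition."""


class DimensionError(PerfutexError, ValueError):
    """Grids that must share geometry do not."""


class MissingVisitError(PerfutexError, ValueError):
    """A patient lacks one of the required pre/post visits."""
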