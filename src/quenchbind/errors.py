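"""Exception hierarchy shared across the package."""


class QuenchBindError(Exception):
    """Base class for all package errors."""


class FormatError(QuenchBindError, ValueError):
    """Malformed input file or table."""


class ValidationError(QuenchBindError, ValueError):
    """Domain-object invariant violated."""


class FitError(QuenchBindError, RuntimeError):
    """A model fit could not be performed or did not converge."""
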