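"""Exception hierarchy shared across the package.

All package-raised errors derive from :class:`EmptyDropsMultiomeError` so
callers (and the CLI) can distinguish user/input problems from genuine bugs.
"""


class EmptyDropsMultiomeError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(EmptyDropsMultiomeError, ValueError):
    """Invalid input data or configuration."""


class ModelFitError(EmptyDropsMultiomeError):
    """A statistical model could not be fitted (e.g. mixture EM failure)."""


class BoundaryError(EmptyDropsMultiomeError):
    """A cluster boundary could not be derived from a fitted model."""
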