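"""Typed errors raised across the package."""


class MolciError(ValueError):
    """Base class for all molci validation and domain errors."""


class InsufficientDataError(MolciError):
    """Too few observations for the requested estimate."""


class SingleClassError(MolciError):
    """A screening operation needs at least one active and one inactive."""


class ResolutionError(MolciError):
    """Requested precision finer than the data or resample grid can support."""


class BoundaryError(MolciError):
    """An estimate sits on a boundary (p in {0, 1}) where a transform blows up."""


class InconsistentErrorBudgetError(MolciError):
    """Stated error components exceed the observed total error."""


class FormatError(MolciError):
    """A data file does not match the expected CSV dialect."""
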