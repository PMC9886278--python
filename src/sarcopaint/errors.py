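"""Exception types shared across the pipeline."""


class SarcopaintError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SarcopaintError):
    """A file does not match the expected on-disk schema."""


class ValidationError(SarcopaintError):
    """In-memory data violate a container invariant."""


class EmptyInputError(SarcopaintError):
    """An operation that requires at least one row received none."""


class BandFitError(SarcopaintError):
    """Gaussian refinement of a single band failed; recorded, not fatal."""


class GridMismatchError(SarcopaintError):
    """Axial profiles do not share a common bin grid."""
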