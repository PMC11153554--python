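"""Exception hierarchy shared by all modules."""


class SGTMError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(SGTMError, ValueError):
    """Input data violates a precondition (empty, non-finite, bad parameter)."""


class ShapeError(InvalidInputError):
    """Array dimensions do not match what a fitted object expects."""


class NotFittedError(SGTMError, RuntimeError):
    """An operation requires a fitted model."""


class InvalidConfigError(SGTMError, ValueError):
    """A configuration value is inconsistent with the data."""


class NotAffineError(SGTMError, RuntimeError):
    """A predictor probed for affine coefficients is not affine."""


class ArchiveError(SGTMError, ValueError):
    """A model archive is corrupted or has an unsupported format version."""
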