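"""Exception hierarchy shared across the pipeline stages."""


class LncprofileError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(LncprofileError, ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(LncprofileError, ValueError):
    """Parsed data violates a structural invariant."""


class EmptyInputError(ValidationError):
    """An input that must contain records is empty."""


class SizingError(LncprofileError, ValueError):
    """A requested simulated geometry does not fit the chromosome."""


class UnscorableError(ValidationError):
    """A transcript has no usable coding-potential predictor value."""


class InsufficientDataError(ValidationError):
    """Too few observations to compute the requested statistic."""
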