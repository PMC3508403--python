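"""Exception hierarchy for the rate-inference pipeline.

Every error raised on a science-path (as opposed to plain bad Python usage)
derives from :class:`BenthicNLossError` so callers can catch the family.
"""


class BenthicNLossError(Exception):
    """Base class for all pipeline errors."""


class InputError(BenthicNLossError, ValueError):
    """Rejected input data (non-finite values, bad schema, bad ranges)."""


class InsufficientDataError(InputError):
    """Too few observations for the requested regression."""


class DegenerateDesignError(InputError):
    """Regression design with zero variance in the predictor."""


class ConfigurationError(BenthicNLossError, ValueError):
    """Missing or out-of-range configuration (volumes, porosity, areas)."""


class DivisionDomainError(BenthicNLossError, ZeroDivisionError):
    """A labeling fraction or copy number of zero where division is required."""


class InfeasibleInversionError(BenthicNLossError, ValueError):
    """No admissible labeling fraction solves the pairing equations.

    Carries the discriminant of the quadratic so callers can report how far
    from feasibility the observation lies.
    """

    def __init__(self, message: str, discriminant: float | None = None):
        super().__init__(message)
        self.discriminant = discriminant


class UndefinedFractionError(BenthicNLossError, ValueError):
    """A fraction A/(A+B) requested with A = B = 0 or all inputs below detection."""


class DegenerateRatioError(BenthicNLossError, ValueError):
    """R29 = p29/p30 undefined because p30 = 0."""


class MissingFieldError(InputError):
    """A required field is absent; the message names the field."""
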