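"""Exception hierarchy for snpmeta."""


class SnpMetaError(Exception):
    """Base class for all snpmeta errors."""


class ValidationError(SnpMetaError, ValueError):
    """Input data violates a documented precondition."""


class ParseError(SnpMetaError, ValueError):
    """A study table could not be parsed."""


class InsufficientStudiesError(SnpMetaError, ValueError):
    """An operation requires more studies than were supplied."""


class UndefinedEffectError(SnpMetaError, ValueError):
    """A 2x2 table admits no finite odds ratio (degenerate margin)."""


class DegenerateRegressionError(SnpMetaError, ValueError):
    """Regression design matrix is singular (e.g. constant precision)."""
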