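"""Exception hierarchy for the surveillance pipeline.

Every failure mode a caller is expected to branch on has its own class;
all inherit from :class:`AqsurveilError`.
"""


class AqsurveilError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(AqsurveilError, ValueError):
    """A configuration value is outside its documented domain."""


class EmptyInputError(AqsurveilError, ValueError):
    """An operation received an empty corpus or dataset."""


class ConsistencyError(AqsurveilError, ValueError):
    """Two inputs that must agree (e.g. city sets) do not."""


class SchemaError(AqsurveilError, ValueError):
    """A file does not match its documented dialect (names the offender)."""


class InsufficientDataError(AqsurveilError, ValueError):
    """Fewer data points than a statistic requires."""


class UndefinedCorrelationError(AqsurveilError, ValueError):
    """Pearson correlation requested on a zero-variance vector."""


class PairingError(AqsurveilError, ValueError):
    """Dependent-correlation comparison on mismatched city sets."""


class DegenerateLabelsError(AqsurveilError, ValueError):
    """Supervised training data contains a single class."""


class ExpressionError(AqsurveilError, ValueError):
    """Malformed or unknown filter-expression node."""


class ModelDependencyError(AqsurveilError, KeyError):
    """A filter references a topic model that is missing or misaligned."""


class DuplicateRecordError(AqsurveilError, ValueError):
    """Two annotation records share the same (message, coder) pair."""


class MissingAdjudicationError(AqsurveilError, ValueError):
    """A coder disagreement has no covering tie-breaker record."""


class KappaUndefinedError(AqsurveilError, ValueError):
    """Chance agreement is 1 so kappa is undefined; carries observed agreement.

    Attributes
    ----------
    p_o : float
        The observed agreement, still well defined.
    """

    def __init__(self, message: str, p_o: float):
        super().__init__(message)
        self.p_o = p_o
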