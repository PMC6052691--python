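class CorescopeError(Exception):
    """Base class for all corescope errors."""


class ParseError(CorescopeError):
    """A file could not be parsed; message names the offending line."""


class ValidationError(CorescopeError):
    """Input violates a documented invariant (bad counts, duplicate IDs...)."""


class UndefinedStatisticError(CorescopeError):
    """A statistic is mathematically undefined for the given input.

    Raised instead of returning a number, e.g. the unbiased inverse Simpson
    estimator on an all-singleton sample, or Bray-Curtis between two empty
    communities.
    """
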