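"""Exception hierarchy for proptab.

All errors raised by the library derive from :class:`ProptabError` so callers
can catch a single base class.  Validation failures are ``ValueError``
subclasses; statistics that are mathematically undefined for a given table
raise :class:`UndefinedStatisticError`.
"""


class ProptabError(Exception):
    """Base class for all proptab errors."""


class DomainError(ProptabError, ValueError):
    """An input is outside its mathematical domain (e.g. a negative count)."""


class DegenerateTableError(ProptabError, ValueError):
    """The table carries no information (all counts zero, or an empty axis
    where one is required)."""


class ZeroMarginError(ProptabError, ValueError):
    """A marginal sum required as a proportional normalizer is zero."""


class UndefinedStatisticError(ProptabError, ValueError):
    """The requested statistic is undefined for this table (e.g. odds ratio
    with ad = bc = 0)."""


class ConvergenceError(ProptabError, RuntimeError):
    """An iterative fit failed to converge (e.g. perfect separation in a
    logistic fit)."""
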