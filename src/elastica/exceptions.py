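"""Exception hierarchy for elastica.

All library errors derive from :class:`ElasticaError` so callers can catch
everything with one clause; the CLI maps parse-type errors to exit code 2 and
numerical failures to exit code 3.
"""


class ElasticaError(Exception):
    """Base class for all elastica errors."""


class InvalidInputError(ElasticaError, ValueError):
    """Malformed data: wrong shape, non-finite entries, asymmetric matrix."""


class InvalidParameterError(ElasticaError, ValueError):
    """A parameter violates its documented range."""


class DuplicateRowError(ElasticaError):
    """A sample's off-self distances are all zero; sigma is undefined."""


class DegenerateAffinityError(ElasticaError):
    """All pairwise weights vanish (e.g. every sample identical)."""


class EmptyFilterError(ElasticaError):
    """Cell/gene filtering removed every row or column."""


class InvalidDirectionError(ElasticaError):
    """Line search was handed a non-descent direction."""


class NumericalError(ElasticaError):
    """A numerical operation (e.g. factorization) failed."""
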