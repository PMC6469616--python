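"""Exception hierarchy.

Everything derives from :class:`PirtfieldError` so callers can catch the
package's failures with one clause; the subclasses mirror the distinct
failure modes of the pipeline stages.
"""


class PirtfieldError(Exception):
    """Base class for all errors raised by pirtfield."""


class ConfigurationError(PirtfieldError):
    """A specification / configuration object is invalid."""


class InputError(PirtfieldError, ValueError):
    """Input data violate a precondition (shape, sign, ordering...)."""


class InsufficientReplicationError(InputError):
    """Too few replicate measurements for the requested statistic."""


class UndefinedSlopeError(PirtfieldError):
    """Major-axis slope is undefined (zero covariance between x and y)."""


class UndefinedTauError(PirtfieldError):
    """Kendall's tau is undefined (one margin entirely tied)."""


class UndefinedBGEError(PirtfieldError):
    """Growth efficiency undefined (production and respiration both zero)."""
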