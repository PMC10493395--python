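"""Exception hierarchy for secflux.

Everything raised on purpose by this package derives from :class:`SecfluxError`,
so callers can catch the package's own failures without swallowing genuine bugs.
"""


class SecfluxError(Exception):
    """Base class for all secflux errors."""


class SchemaError(SecfluxError):
    """An input table is missing a required column or has an unusable layout."""


class EmptyInputError(SecfluxError):
    """An input file or collection contained no data."""


class TraceValidationError(SecfluxError):
    """A kinetic trace violates its invariants (length, monotone time, finiteness)."""


class ParameterError(SecfluxError):
    """A function argument is outside its documented domain."""


class NoGrowthError(SecfluxError):
    """A trace shows no signal growth (plateau not above baseline).

    Raised by normalization; the caller decides whether this means
    complete inhibition of aggregation.
    """


class GridError(SecfluxError):
    """Replicate traces do not share a common time grid and interpolation is off."""


class WindowError(SecfluxError):
    """An early-time fitting window could not be selected."""


class DataError(SecfluxError):
    """Not enough data points for the requested fit."""


class FitError(SecfluxError):
    """A least-squares fit could not be performed (singular design etc.)."""


class NonIdentifiableError(FitError):
    """The data contain no transition; dose-response parameters are not identifiable."""


class NormalizationError(SecfluxError):
    """Relative-rate normalization is impossible (e.g. control entirely inhibited)."""


class DegenerateVarianceError(SecfluxError):
    """All groups have zero within-group variance; ANOVA is undefined."""
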