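"""Exception hierarchy.

Validation problems (bad tables, out-of-range parameters, missing years)
raise :class:`InvalidInputError`; conditions that make the requested
computation mathematically undefined (zero residual variance, excluded
country) raise dedicated subclasses of :class:`ComputationError`.  The CLI
maps the two branches to distinct exit codes.
"""


class ImpactError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InvalidInputError(ImpactError):
    """Malformed or out-of-contract input (bad file, bad parameter)."""

    exit_code = 2


class MissingDataError(InvalidInputError):
    """A required year/month/day is absent from the input."""


class ComputationError(ImpactError):
    """The computation is undefined for otherwise well-formed input."""

    exit_code = 3


class DegenerateVarianceError(ComputationError):
    """Residual standard deviation is zero; the anomaly is undefined."""


class NoCultivationError(ComputationError):
    """Both irrigated and rainfed area fractions are zero."""


class CountryExcludedError(ComputationError):
    """Country fails the hydropower plant-count / installed-capacity filter."""
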