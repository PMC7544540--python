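"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`SmokeMrError`, so callers (and the
CLI) can catch one type and still report which stage failed.
"""


class SmokeMrError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(SmokeMrError):
    """A config file, column map, or parameter set is invalid."""


class DataError(SmokeMrError):
    """An input table violates its contract (duplicates, bad ranges, ...)."""


class DomainError(SmokeMrError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class InstrumentSelectionError(SmokeMrError):
    """Instrument selection produced an unusable (empty) set."""


class HarmonizationError(SmokeMrError):
    """Harmonization dropped every instrument."""


class EstimatorError(SmokeMrError):
    """An estimator cannot run on the data provided."""


class CollinearityError(EstimatorError):
    """Design matrix is rank deficient; named columns are not separable."""
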