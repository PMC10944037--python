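"""Exception hierarchy.

Three broad classes map onto CLI exit codes: configuration problems (bad
column maps, thresholds outside their domain), data problems (empty inputs,
no overlapping variants), and numerical problems (singular matrices,
non-convergent optimizers).
"""


class ProteoMRError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ProteoMRError):
    """Invalid user-supplied configuration (column map, threshold, prior)."""


class DataError(ProteoMRError):
    """Input data unusable for the requested operation."""


class EmptyInputError(DataError):
    """A file or table contained zero valid rows."""


class EmptyOverlapError(DataError):
    """Exposure and outcome summary statistics share no variants."""


class UnidentifiableModelError(DataError):
    """Model cannot be identified from the data (e.g. no events)."""


class InsufficientInstrumentsError(DataError):
    """Too few qualifying variants for a stable fit."""


class NumericalError(ProteoMRError):
    """Numerical failure (singular system, ill-conditioning)."""


class ConvergenceFailure(NumericalError):
    """Iterative optimizer failed to converge within its budget."""
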