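"""Exception hierarchy.

Grouped by how the command-line layer maps failures to exit codes:
configuration problems (bad parameters, impossible requests), data/format
problems (unreadable or inconsistent input files), and estimation failures
(a trend or statistic that cannot be computed from the data given).
"""


class MsDriftError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MsDriftError):
    """Invalid parameter value or an impossible configuration request."""


class ParameterError(ConfigurationError):
    """A trend/smoother parameter outside its valid range."""


class FormatError(MsDriftError):
    """A file does not conform to the expected tabular layout."""


class ConsistencyError(MsDriftError):
    """Linked inputs disagree (e.g. sample ids differ between files)."""


class EstimationError(MsDriftError):
    """A trend fit could not be computed (too few points, degenerate data)."""


class EvaluationError(MsDriftError):
    """A performance metric could not be computed."""


class OptimizationError(MsDriftError):
    """Every candidate in a parameter grid failed."""
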