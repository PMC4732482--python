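"""Exception hierarchy.

Everything raised on purpose derives from :class:`AcclimError`, so the CLI can
map validation failures to exit code 2 without catching programming errors.
"""


class AcclimError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(AcclimError, ValueError):
    """Invalid generator or run configuration; message names the field."""


class DataError(AcclimError, ValueError):
    """Malformed or insufficient input data (too few samples, id mismatch...)."""


class GeometryError(DataError):
    """Impossible chamber geometry, e.g. fish volume >= chamber volume."""


class ParameterError(AcclimError, ValueError):
    """Out-of-domain scalar parameter (negative rate, nonpositive MMR...)."""


class DomainError(AcclimError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class TransformError(DomainError):
    """A requested transform (log10) is undefined for the supplied values."""


class DesignError(AcclimError, ValueError):
    """Factorial design problem: empty cell, <2 levels, rank deficiency."""


class SchemaError(AcclimError, OSError):
    """Input file missing or not matching the expected CSV schema."""
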