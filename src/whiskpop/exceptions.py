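"""Package-level exception types."""


class WhiskpopError(Exception):
    """Base class for all package errors."""


class ConfigurationError(WhiskpopError):
    """Inconsistent or infeasible configuration."""


class InputError(WhiskpopError):
    """Invalid input data (wrong sign, shape or domain)."""


class SchemaError(WhiskpopError):
    """A required table column is missing."""


class DegenerateDataError(WhiskpopError):
    """Input is degenerate for the requested operation (e.g. constant trace)."""


class CollinearityError(WhiskpopError):
    """A design-matrix column is constant or linearly dependent."""
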