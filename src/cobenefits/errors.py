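"""Exception hierarchy for the co-benefit pipeline.

Each stage raises a distinct subclass so the CLI can map failures to
exit codes: validation (bad values), alignment (mismatched keys/grids),
and configuration (missing parameters or files).
"""


class CobenefitsError(Exception):
    """Base class for all pipeline errors."""


class InputError(CobenefitsError, ValueError):
    """A numeric input violates a precondition (non-finite, negative, ...)."""


class FormatError(CobenefitsError, ValueError):
    """A tabular input file is malformed (missing column, duplicate key, ...)."""


class ParameterLookupError(CobenefitsError, KeyError):
    """A requested (disease, age group) parameter set does not exist."""


class RegistrationError(CobenefitsError, ValueError):
    """Concentration and population grids are not co-registered."""


class WeightingError(CobenefitsError, ValueError):
    """A weighted average is undefined (zero total weight)."""


class AlignmentError(CobenefitsError, ValueError):
    """Two tables that must share keys do not align."""


class ConfigurationError(CobenefitsError, ValueError):
    """A run configuration is inconsistent or incomplete."""
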