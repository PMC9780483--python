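"""Exception hierarchy shared by all refstab modules."""


class RefstabError(Exception):
    """Base class for all refstab errors."""


class FormatError(RefstabError):
    """Malformed input table (duplicate keys, wrong columns, ...)."""


class ValidationError(RefstabError):
    """Input parsed but violates a domain invariant (e.g. Cp out of range)."""


class MissingDataError(RefstabError):
    """A required value is absent (empty replicate group, NaN cell, ...)."""


class ParameterError(RefstabError):
    """A numeric parameter is outside its admissible range."""


class InsufficientDataError(RefstabError):
    """Too few genes, samples, or points for the requested computation."""


class ConfigurationError(RefstabError):
    """Invalid run configuration (bad method subset, gene-count limit, ...)."""


class FitError(RefstabError):
    """A regression/calibration fit cannot be performed."""
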