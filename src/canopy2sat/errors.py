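"""Exception hierarchy shared across the package."""


class Canopy2SatError(Exception):
    """Base class for package errors."""


class ConfigurationError(Canopy2SatError):
    """Unknown stage/sensor or invalid generator/pipeline configuration."""


class FormatError(Canopy2SatError):
    """Malformed on-disk library, table, or sensor file."""


class DegenerateBandError(Canopy2SatError):
    """Spectral response function with zero total weight."""


class UndefinedIndexError(Canopy2SatError):
    """Normalized-difference index with a zero-sum denominator."""


class UndefinedCorrelationError(Canopy2SatError):
    """Correlation requested on a zero-variance vector."""


class ScreeningError(Canopy2SatError):
    """Band-pair screening could not produce any defined correlation."""


class AlignmentError(Canopy2SatError):
    """Sample ids disagree between tables that must be paired."""
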