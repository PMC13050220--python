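"""Exception hierarchy shared across the package."""


class CanosifError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(CanosifError, ValueError):
    """An input value makes the requested computation undefined."""


class WindowError(CanosifError, ValueError):
    """A spectral window does not intersect the data grid as required."""


class IllConditionedError(CanosifError, ValueError):
    """The least-squares design is rank deficient or unusable."""


class PolarConditionError(CanosifError, ValueError):
    """Sunset hour angle undefined: polar day or night at this latitude."""


class SaturationError(CanosifError, ValueError):
    """fPAR at or above 1 cannot be inverted to a finite LAI."""


class InsufficientDataError(CanosifError, ValueError):
    """Too few observations for the requested fit."""


class DegenerateFitError(CanosifError, ValueError):
    """Regressor is constant; slope and R^2 are undefined."""


class ConfigError(CanosifError, ValueError):
    """Inconsistent simulation or analysis configuration."""
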