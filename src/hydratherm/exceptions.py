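"""Exception hierarchy."""


class HydrathermError(Exception):
    """Base class for all package-specific errors."""


class DomainError(HydrathermError, ValueError):
    """Non-physical input (negative temperature, zero pressure, ...)."""


class ConfigurationError(HydrathermError, ValueError):
    """Inconsistent simulator or pipeline configuration."""


class InsufficientDataError(HydrathermError, ValueError):
    """Too few usable points/bins to perform the requested computation."""


class FitError(HydrathermError, ValueError):
    """Singular or otherwise infeasible regression problem."""
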