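"""Exception hierarchy shared across the package."""


class HemoprevError(Exception):
    """Base class for all package errors."""


class ConfigError(HemoprevError, ValueError):
    """Invalid configuration (bad proportions, impossible parameter values)."""


class DomainError(HemoprevError, ValueError):
    """A value outside the supported domain (unknown level, p-value outside [0,1])."""


class DataError(HemoprevError, ValueError):
    """Invalid data content (missing fields, nonpositive measurements, empty samples)."""


class EstimationError(HemoprevError, RuntimeError):
    """An estimation step cannot proceed (rank-deficient design, no discriminative power)."""
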