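"""Exception hierarchy for design-engine failure modes."""


class RbgDesignError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RbgDesignError, ValueError):
    """A numeric argument is outside its valid domain."""


class UnachievablePowerError(RbgDesignError):
    """No finite sample size attains the requested power (e.g. d = 0)."""


class InfeasibleDesignError(RbgDesignError):
    """The participant budget cannot seat the requested stage(s)."""


class UndefinedEffectError(RbgDesignError):
    """Standardized effect is undefined (zero pooled standard deviation)."""


class InfeasibleLDError(RbgDesignError):
    """Requested r-squared exceeds the Frechet bound for the allele frequencies."""


class InsufficientPoolError(RbgDesignError):
    """The genotyped pool cannot supply the requested recall group sizes."""


class ConfigError(RbgDesignError):
    """A configuration file failed validation."""
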