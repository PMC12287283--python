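"""Exception hierarchy shared across the pipeline."""


class EnaDecayError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(EnaDecayError, ValueError):
    """A value violates an operation's preconditions (e.g. W > U, U = 0)."""


class ConfigurationError(EnaDecayError):
    """Run configuration or data wiring is inconsistent (missing pairs, unknown ids)."""


class SaturatedAssayError(EnaDecayError):
    """A ddPCR well is saturated (no negative droplets in a required category),
    so the Poisson occupancy is unquantifiable."""


class InvalidComparisonError(EnaDecayError):
    """Model fits being compared do not share an identical well set."""


class ConvergenceError(EnaDecayError):
    """MCMC diagnostics failed and the caller required convergence."""
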