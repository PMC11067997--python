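"""Exception hierarchy for the zsd package."""


class ZsdError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(ZsdError):
    """A configuration value violates its declared range or type."""


class ValidationError(ZsdError):
    """Input data violate a structural invariant (named offender included)."""


class InvalidCrossError(ZsdError):
    """A cross was requested between incompatible parents (e.g. same sex)."""


class UndefinedStatisticError(ZsdError):
    """A statistic is undefined on the given input (e.g. zero comparable sites)."""


class ImpossibleSampleError(ZsdError):
    """A resampling scheme cannot produce any valid draw (e.g. one allele only)."""
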