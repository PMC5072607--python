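"""Exception hierarchy shared across the package."""


class ChantError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ChantError, ValueError):
    """An invalid parameter value in a config object or function argument."""


class DegenerateDataError(ChantError, ValueError):
    """A statistic is undefined on the supplied data (single-class labels,
    zero variance, curves that never cross, ...)."""


class UndefinedMetricError(ChantError, ValueError):
    """A 2x2 accuracy metric has a zero denominator."""
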