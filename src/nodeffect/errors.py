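"""Exception hierarchy shared across the package."""


class NodEffectError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(NodEffectError, ValueError):
    """A function argument violates its contract; message names the field."""


class ValidationError(NodEffectError, ValueError):
    """Input data violate a structural invariant (e.g. non-positive RRI)."""


class FormatError(NodEffectError, ValueError):
    """A file could not be parsed in the declared dialect."""


class ConfigurationError(NodEffectError, ValueError):
    """A study/run configuration is inconsistent or incomplete."""


class InsufficientDataError(NodEffectError, ValueError):
    """Too few samples to compute the requested statistic."""


class DegenerateDataError(NodEffectError, ValueError):
    """Data are degenerate for the statistic (e.g. all values identical)."""
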