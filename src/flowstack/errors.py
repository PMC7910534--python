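"""Exception hierarchy shared across flowstack modules."""


class FlowstackError(Exception):
    """Base class for all flowstack errors."""


class InvalidInputError(FlowstackError, ValueError):
    """Malformed data: shape mismatches, negative counts, bad coordinates."""


class UndefinedFluxError(FlowstackError, ValueError):
    """A flux equation was evaluated where it is mathematically undefined
    (e.g. zero distance with a positive distance exponent)."""


class InvalidParameterError(FlowstackError, ValueError):
    """A model parameter violates its domain (e.g. selection λ outside (0,1))."""


class ConfigurationError(FlowstackError, ValueError):
    """Unknown model identifier or inconsistent run configuration."""


class ScenarioError(FlowstackError, ValueError):
    """A synthetic scenario produced unusable output (e.g. overflowing means)."""
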