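"""Exception hierarchy shared across the package."""


class GrainRiskError(Exception):
    """Base class for all grainrisk errors."""


class SchemaError(GrainRiskError):
    """A required column or config block is missing or misnamed."""


class ValidationError(GrainRiskError):
    """A data row or field violates an invariant (row index in message)."""


class ConfigError(GrainRiskError):
    """A parameter configuration entry is malformed; message names the key path."""


class ParameterError(GrainRiskError):
    """An exposure/risk parameter is missing or out of its valid range."""


class EmptyGroupError(GrainRiskError):
    """An operation was requested on an empty sample group."""


class DegenerateInputError(GrainRiskError):
    """Input admits no well-defined answer (e.g. constant regressor)."""


class SpecError(GrainRiskError):
    """A synthetic-data specification is infeasible."""
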