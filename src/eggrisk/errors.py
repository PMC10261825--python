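"""Exception hierarchy for eggrisk."""


class EggRiskError(Exception):
    """Base class for all eggrisk errors."""


class FormatError(EggRiskError):
    """A file or stream does not conform to the expected format."""


class ValidationError(EggRiskError):
    """Input data violates an invariant (negative concentration, missing LOQ, ...)."""


class ConfigError(EggRiskError):
    """A configuration value is missing, unknown, or inconsistent."""


class MissingAnalyteError(ValidationError):
    """The requested analyte has no records in the table."""


class SamplingError(EggRiskError):
    """A Monte Carlo sampling request cannot be satisfied (infeasible truncation)."""


class GenerationError(EggRiskError):
    """The synthetic-data configuration is infeasible."""
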