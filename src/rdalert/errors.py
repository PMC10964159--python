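"""Exception hierarchy for rdalert."""


class RDAlertError(Exception):
    """Base class for all rdalert errors."""


class ConfigError(RDAlertError):
    """Invalid generator or analysis configuration."""


class SchemaError(RDAlertError):
    """Cohort table does not conform to the documented column schema."""


class ValidationError(RDAlertError):
    """Cohort data fails a value-level validation rule."""


class EstimationError(RDAlertError):
    """An estimator could not be computed (singular design, empty bins...)."""


class InsufficientDataError(EstimationError):
    """Too few observations with positive weight to fit the model."""


class PipelineError(RDAlertError):
    """A pipeline stage failed; carries the stage name in the message."""
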