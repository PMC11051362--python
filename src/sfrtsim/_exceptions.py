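"""Exception hierarchy.

Two broad failure classes map onto the CLI exit codes: configuration
problems (bad scenario files, invalid parameter combinations; exit 2) and
model-domain problems (inputs outside the mathematical domain of the model,
e.g. a volume at or beyond the lethal volume; exit 3).
"""


class SFRTSimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SFRTSimError):
    """Invalid scenario configuration or parameter combination."""


class VertexOverflowError(ConfigurationError):
    """Vertex volume attributed to a compartment exceeds that compartment."""


class ModelDomainError(SFRTSimError):
    """Input outside the mathematical domain of the model."""


class CalibrationError(ModelDomainError):
    """Radiosensitivity calibration is singular or non-physical."""


class NoRegrowthError(ModelDomainError):
    """Recovery regime: the regrowth time does not exist (A >= ln(V_inf/V))."""
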