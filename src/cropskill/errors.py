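"""Exception hierarchy shared across the package."""


class CropSkillError(Exception):
    """Base class for all package errors."""


class ParameterError(CropSkillError, ValueError):
    """A generator or model parameter is outside its valid range."""


class CoverageError(CropSkillError, ValueError):
    """A weather series does not cover the requested window."""


class ClassificationError(CropSkillError, ValueError):
    """An index value needed for phase classification is missing."""


class InsufficientAnaloguesError(CropSkillError, ValueError):
    """No analogue years remain after leave-one-out exclusion."""


class UndefinedMetricError(CropSkillError, ValueError):
    """A verification metric is undefined for the supplied series
    (e.g. zero reference Brier score, or every forecast at the base rate)."""


class InputError(CropSkillError, ValueError):
    """Malformed or empty input series."""


class OptimizationError(CropSkillError, ValueError):
    """Empty candidate set or unresolvable strategy optimisation."""


class ConfigError(CropSkillError, ValueError):
    """Invalid experiment configuration."""


class DependencyError(CropSkillError, RuntimeError):
    """A pipeline stage's upstream artifact is missing or inconsistent."""
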