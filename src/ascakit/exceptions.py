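"""Exception hierarchy used across ascakit."""


class AscakitError(Exception):
    """Base class for all ascakit errors."""


class ConfigurationError(AscakitError):
    """Invalid configuration value; the message names the offending field."""


class FormatError(AscakitError):
    """Malformed tabular input; the message carries row/column location."""


class AlignmentError(AscakitError):
    """Feature table and design table do not describe the same samples."""


class DegenerateSampleError(AscakitError):
    """A sample cannot be normalized (e.g. zero internal-standard mean)."""


class ConstantColumnError(AscakitError):
    """Autoscaling requested on one or more zero-variance columns."""


class DesignError(AscakitError):
    """The experimental design is unusable for the requested model."""


class UnbalancedDesignError(DesignError):
    """Multi-factor decomposition requested on an unbalanced design."""


class NoEffectVarianceError(AscakitError):
    """A component model was requested for an all-zero effect matrix."""


class SingularWithinError(AscakitError):
    """The (un)regularized within-group covariance is singular."""
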