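"""Exception hierarchy for the pipeline."""


class LipidsigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LipidsigError):
    """Invalid configuration value; the message names the offending field."""


class PanelFormatError(LipidsigError):
    """Malformed panel file or inconsistent panel components."""


class PolicyError(LipidsigError):
    """Missingness policy cannot be evaluated (e.g. an empty group)."""


class ImputationError(LipidsigError):
    """Imputation cannot be completed for a cell; names metabolite/plate."""


class BatchCorrectionError(LipidsigError):
    """Batch correction preconditions violated (e.g. a plate with < 2 samples)."""


class NormalizationError(LipidsigError):
    """Permille normalization failed (e.g. zero row total)."""
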