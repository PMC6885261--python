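"""Exception hierarchy for the toolkit."""


class EmgkitError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(EmgkitError, ValueError):
    """Invalid parameter or hyperparameter value."""


class ConfigurationError(EmgkitError, ValueError):
    """Invalid or inconsistent configuration (unknown keys, bad combinations)."""


class ManifestError(EmgkitError):
    """Malformed recording manifest."""


class SampleParseError(EmgkitError):
    """Non-numeric sample in a recording file; message names the line."""


class FramingError(EmgkitError):
    """Signal too short to cut a single frame (or bad framing parameters)."""


class DecompositionError(EmgkitError):
    """Wavelet-packet decomposition cannot be applied to this frame."""


class ReconstructionError(EmgkitError):
    """Incomplete or inconsistent subband set for reconstruction."""


class TableError(EmgkitError):
    """Malformed feature table (mixed frame lengths, missing label column...)."""


class TrainingError(EmgkitError):
    """Base-learner training failed (e.g. a class absent from the data)."""


class PredictionError(EmgkitError):
    """Prediction requested from an unusable model (e.g. empty committee)."""


class EvaluationError(EmgkitError):
    """Metric computation impossible (empty matrix, single-class truth...)."""


class StratificationError(EvaluationError):
    """A class is rarer than the number of folds."""
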