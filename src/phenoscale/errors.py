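"""Exception hierarchy for the monitoring pipeline."""


class PhenoscaleError(Exception):
    """Base class for all package errors."""


class ParameterError(PhenoscaleError, ValueError):
    """An input parameter violates its documented domain."""


class ConfigurationError(PhenoscaleError, ValueError):
    """A configuration is internally inconsistent (e.g. an irrigation dose
    that can never fit the substrate's water capacity)."""


class GapError(PhenoscaleError, ValueError):
    """A sensor channel cannot be gap-filled (all samples invalid, or the
    stream does not start/end with a valid sample)."""


class FitError(PhenoscaleError, RuntimeError):
    """Nonlinear least squares failed to converge from every attempted start."""

    def __init__(self, message, starts=None):
        super().__init__(message)
        self.starts = list(starts) if starts is not None else []


class TrainingError(PhenoscaleError, RuntimeError):
    """Neural-network training diverged (non-finite loss)."""

    def __init__(self, message, epoch=None):
        super().__init__(message)
        self.epoch = epoch


class EvaluationError(PhenoscaleError, ValueError):
    """Too little overlap between estimate and reference to compute metrics."""


class DatasetError(PhenoscaleError, ValueError):
    """A dataset construction yielded no usable samples."""


class ProtocolError(PhenoscaleError, ValueError):
    """An evaluation protocol constraint was violated (e.g. overlapping
    train/test seasons in a cross-season experiment)."""


class PipelineError(PhenoscaleError, RuntimeError):
    """A pipeline stage is missing an upstream artifact."""

    def __init__(self, message, stage=None):
        super().__init__(message)
        self.stage = stage
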