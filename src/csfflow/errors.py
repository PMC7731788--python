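"""Exception types shared across the pipeline stages."""


class CsfFlowError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(CsfFlowError, ValueError):
    """A synthetic scene specification violates its invariants."""


class InvalidParameterError(CsfFlowError, ValueError):
    """A stage parameter violates a documented precondition."""


class EmptyRegionError(CsfFlowError, ValueError):
    """A region selection contains no pixels, vectors or samples."""


class InsufficientDataError(CsfFlowError, ValueError):
    """Too few observations to run an estimator (e.g. GP fit needs >= 5)."""


class DegenerateInputError(CsfFlowError, ValueError):
    """Statistically degenerate input (e.g. all paired differences zero)."""


class InvalidWeightsError(CsfFlowError, ValueError):
    """All observation weights are zero."""


class PipelineStageError(CsfFlowError, RuntimeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
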