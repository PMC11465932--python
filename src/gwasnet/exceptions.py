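"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """Raised when an input table, graph or configuration fails validation."""


class PipelineStageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
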