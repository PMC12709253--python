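"""Exception hierarchy for the beat-analysis pipeline."""


class AxobeatError(Exception):
    """Base class for all package errors."""


class ParameterError(AxobeatError, ValueError):
    """An invalid parameter value; ``field`` names the offending parameter."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class InputDataError(AxobeatError, ValueError):
    """Input data violate a structural precondition (too few points, no oscillation...)."""


class StageError(AxobeatError, RuntimeError):
    """A pipeline stage failed; carries the stage name and context."""

    def __init__(self, stage: str, message: str, context: str = ""):
        self.stage = stage
        self.context = context
        tail = f" [{context}]" if context else ""
        super().__init__(f"stage '{stage}': {message}{tail}")
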