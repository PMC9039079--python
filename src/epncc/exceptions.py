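"""Exception types shared across the package."""


class EPNCCError(ValueError):
    """Base class for all package-specific errors."""


class ParameterError(EPNCCError):
    """An argument is outside its documented domain."""


class DegenerateInputError(EPNCCError):
    """The input signal is degenerate (empty, constant, or all-zero) for
    an operation that has no defined output on it."""


class TrainingError(EPNCCError):
    """Network optimization failed (non-finite loss); carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
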