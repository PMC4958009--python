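"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative scheme fails to converge.

    Carries the last iterate in ``last`` so callers can inspect or
    salvage partial progress.
    """

    def __init__(self, message, last=None):
        super().__init__(message)
        self.last = last
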