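"""Package exceptions.

``DomainError`` marks inputs outside a function's mathematical domain,
``ValidationError`` marks malformed input files or tables, ``FitError``
marks nonlinear-fit failures (it carries the last iterate), and
``PipelineError`` wraps a stage failure in the end-to-end pipeline.
"""

from __future__ import annotations

__all__ = ["DomainError", "ValidationError", "FitError", "PipelineError"]


class DomainError(ValueError):
    """Input outside the mathematical domain of an operation."""


class ValidationError(ValueError):
    """Malformed or out-of-contract input data."""


class FitError(RuntimeError):
    """Nonlinear least-squares failure; ``last_params`` holds the last iterate."""

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
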