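"""Error hierarchy shared by every pipeline stage.

Exit-code mapping used by the CLI: validation errors -> 2, I/O errors -> 3,
degenerate-input errors -> 4.
"""

from __future__ import annotations


class OctaFractalError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OctaFractalError, ValueError):
    """Input violates a documented precondition or invariant."""


class SchemaError(ValidationError):
    """A table is missing required columns or has malformed values."""


class DegenerateInputError(OctaFractalError, ValueError):
    """Input is technically well-formed but carries no usable signal
    (e.g. a constant image offered to Otsu thresholding)."""


class EmptyMaskError(DegenerateInputError):
    """A binary map or skeleton with no foreground pixels where at least
    one is required."""


class StageError(OctaFractalError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}': {cause}")
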