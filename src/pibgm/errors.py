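"""Exception hierarchy for the pibgm package.

Every error raised deliberately by the library derives from :class:`PibgmError`
so callers (and the CLI) can distinguish domain failures from programming bugs.
"""

from __future__ import annotations


class PibgmError(Exception):
    """Base class for all pibgm domain errors."""


class ConfigError(PibgmError):
    """Invalid or inconsistent configuration / parameters."""


class GridMismatchError(PibgmError):
    """Two grid-aligned objects do not share shape/geometry."""


class EmptyMaskError(PibgmError):
    """A mask that must be non-empty came out empty."""


class EmptyRegionError(PibgmError):
    """A named region required for a statistic holds no voxels."""

    def __init__(self, region: str, message: str | None = None):
        self.region = region
        super().__init__(message or f"region {region!r} is empty")


class HistogramFitError(PibgmError):
    """Two-Gaussian histogram fit failed to converge.

    Carries the last parameter iterate (if any) and the residual norm so a
    caller can inspect how far the optimizer got.
    """

    def __init__(self, message: str, last_params=None, residual=None):
        self.last_params = last_params
        self.residual = residual
        super().__init__(message)


class DegenerateHistogramError(HistogramFitError):
    """Histogram lacks the two separated modes the model requires."""


class ContourVanishedError(PibgmError):
    """Active-contour evolution emptied one of its two regions."""

    def __init__(self, iteration: int, which: str):
        self.iteration = iteration
        self.which = which
        super().__init__(
            f"contour vanished at iteration {iteration}: {which} region is empty"
        )


class StageError(PibgmError):
    """A pipeline stage failed; wraps the underlying cause with context."""

    def __init__(self, stage: str, message: str, cause: Exception | None = None):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {message}")
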