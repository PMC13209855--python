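"""Exception hierarchy for capmetrics.

All package-specific failures derive from :class:`CapmetricsError` so
callers can catch the whole family with one clause.
"""


class CapmetricsError(Exception):
    """Base class for all capmetrics errors."""


class AssayInconsistencyError(CapmetricsError, ValueError):
    """A bench measurement violates a physical constraint (e.g. dried mass
    exceeding initial mass, surface oil exceeding total oil)."""


class ConvergenceError(CapmetricsError, ValueError):
    """A tapped-density volume series has not settled to <1% relative change."""


class PlacementError(CapmetricsError, RuntimeError):
    """Rejection sampling could not place the requested number of particles
    under the overlap constraint.  Carries the number actually placed."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"could only place {placed} of {requested} particles under the "
            f"overlap constraint; reduce density or relax the constraint"
        )


class SegmentationError(CapmetricsError, RuntimeError):
    """A segmentation backend failed; the message names the backend."""


class EmptyTableError(CapmetricsError, ValueError):
    """An operation that needs at least one retained particle received none."""


class CalibrationError(CapmetricsError, ValueError):
    """Calibration fitting is impossible (too few levels, degenerate design)."""


class DegenerateVarianceError(CapmetricsError, ValueError):
    """Within-group variance is zero; F statistics and Tukey tests undefined."""


class StageError(CapmetricsError, RuntimeError):
    """A pipeline stage failed; names the stage and the offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
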