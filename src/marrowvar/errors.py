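"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input data violates a contract (range, shape, schema)."""


class ShapeMismatchError(ValidationError):
    """A volume and its mask (or two paired grids) disagree in shape."""


class FlatTrajectoryError(RuntimeError):
    """Axial trajectory has no detectable proximal/distal contrast.

    Carries the plateau gap so callers can decide to treat the whole
    mask as a single region.
    """

    def __init__(self, message: str, level_gap: float):
        super().__init__(message)
        self.level_gap = float(level_gap)


class DegenerateROIError(ValueError):
    """Fewer than two voxel values remain after trimming."""

    def __init__(self, message: str, n_total: int, n_retained: int):
        super().__init__(message)
        self.n_total = int(n_total)
        self.n_retained = int(n_retained)
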