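"""Exception types shared across the package."""


class OutletPlanError(Exception):
    """Base class for all package-specific errors."""


class InputError(OutletPlanError):
    """A required input file or layer is missing or unreadable."""


class UnitError(OutletPlanError):
    """Coordinates look geographic (lon/lat degrees) instead of planar feet."""


class ValidationError(OutletPlanError):
    """A domain invariant is violated (duplicate ids, bad enum value, ...)."""


class ConfigError(OutletPlanError):
    """A configuration mapping contains unknown or invalid keys."""


class CapacityError(OutletPlanError):
    """The hard-core sampler could not place the requested number of points.

    Attributes
    ----------
    placed : int
        Number of points successfully placed before giving up.
    requested : int
        Number of points asked for.
    """

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"could only place {placed} of {requested} points at the "
            "required separation; extent too small or separation too large"
        )


class InsufficientDataError(OutletPlanError):
    """A statistic is undefined for the given input size (e.g. < 2 points)."""
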