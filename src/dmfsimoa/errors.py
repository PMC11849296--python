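"""Exception hierarchy for dmfsimoa.

All errors derive from :class:`DmfError` (a ``ValueError``) so callers can
catch the package's failures with a single except clause while standard
``ValueError`` handling still applies.
"""


class DmfError(ValueError):
    """Base class for all dmfsimoa errors."""


class InvalidGeometryError(DmfError):
    """A geometric parameter is non-physical (non-positive length etc.)."""


class DegenerateGeometryError(DmfError):
    """A geometry that makes the model degenerate (e.g. densifying electrode
    at least as wide as the destination electrode, leaving no neck)."""


class InvalidInputError(DmfError):
    """A non-geometric input violates its precondition."""


class InsufficientDataError(DmfError):
    """Not enough samples to evaluate a windowed statistic."""


class IncompleteCycleError(DmfError):
    """The capacitance stream ended before a loading cycle completed."""

    def __init__(self, phase: str, cycle_index: int):
        self.phase = phase
        self.cycle_index = cycle_index
        super().__init__(
            f"capacitance stream ended during phase {phase!r} of cycle "
            f"{cycle_index} (controller starved: stability/rise condition "
            f"never met before the stream ran out)"
        )


class SaturationError(DmfError):
    """All beads are signal-positive; the Poisson-corrected AEB estimator
    -ln(1 - f_on) is undefined at f_on = 1."""


class PlacementError(DmfError):
    """Could not place the requested number of beads at the requested
    minimum separation."""
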