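"""Exception hierarchy shared by all analysis modules."""


class VitellometricsError(Exception):
    """Base class for all package-specific errors."""


class BondNumberError(VitellometricsError):
    """Bond number outside the supported range of the drop-shape solver."""

    def __init__(self, bond_number, lo, hi):
        self.bond_number = bond_number
        self.supported = (lo, hi)
        super().__init__(
            f"Bond number {bond_number:.3g} outside supported range [{lo:g}, {hi:g}]"
        )


class ShapeSolverError(VitellometricsError):
    """Non-convergence of the drop-shape boundary-value solve.

    Carries the last continuation state so a caller can diagnose where the
    solve stalled.
    """

    def __init__(self, message, last_bond_number=None):
        self.last_bond_number = last_bond_number
        super().__init__(message)


class BracketError(VitellometricsError):
    """A root bracket does not contain a sign change of the residual."""


class DegenerateProfileError(VitellometricsError):
    """A drop profile with zero diameter (or otherwise unusable geometry)."""


class EnergyMinimizationError(VitellometricsError):
    """The constrained energy minimizer failed to converge."""


class IncompleteTraceError(VitellometricsError):
    """A scale trace missing the events needed for the requested tension."""


class TraceQCError(VitellometricsError):
    """A measurement trace that fails basic quality control."""


class InsufficientDataError(VitellometricsError):
    """Too few samples/frames for the requested estimate."""
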