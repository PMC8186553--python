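"""Exception hierarchy for the bench-dehydration pipeline."""


class AEHydroError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(AEHydroError, ValueError):
    """Input data violate a precondition (lengths, signs, degenerate values)."""


class InvalidWindowError(InvalidInputError):
    """A derivative window is shorter than two bins or not representable on the grid."""


class OutOfRangeError(InvalidInputError):
    """A requested level or time lies outside the range of the data."""


class ConvergenceError(AEHydroError):
    """Optimizer failed to converge; ``best_fit`` carries the best model found."""

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


class NoEndpointError(AEHydroError):
    """No post-peak local maximum of the third derivative (recording too short or flat)."""


class MissingThresholdError(AEHydroError):
    """The vulnerability curve never reaches the requested PLC level."""

    def __init__(self, level, message=None):
        super().__init__(message or f"PLC never reaches {level}%")
        self.level = level


class AlignmentError(AEHydroError):
    """Two series do not share a compatible grid or time range."""


class DegeneratePhaseError(AEHydroError):
    """Desorption curve has no resolvable phase structure (e.g. purely linear)."""


class InsufficientPhaseDataError(AEHydroError):
    """Fewer than the minimum number of points fall inside a phase window."""


class MissingMeasurementError(AEHydroError):
    """No vessel record carries the measurements required for the trait."""


class EmptySelectionError(AEHydroError):
    """Organ filter or other selection produced an empty record set."""
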