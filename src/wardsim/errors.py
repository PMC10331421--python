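"""Named failure types.

Every validation or lookup failure in the package raises one of these, so
callers (and the CLI) can distinguish bad input (usage) from runtime faults.
"""


class WardSimError(Exception):
    """Base class for all wardsim failures."""


class FloorPlanError(WardSimError):
    """Base class for floor-plan validation failures."""


class NonRectangularMapError(FloorPlanError):
    """Map rows differ in length."""


class LocationOnWallError(FloorPlanError):
    """A named destination or nurse station sits on a non-walkable cell."""


class UnreachableDestinationError(FloorPlanError):
    """Named locations are not mutually reachable over walkable cells."""


class RoutingError(WardSimError):
    """No walkable route exists between the requested cells."""


class ConfigError(WardSimError):
    """Simulation configuration is invalid or incomplete."""


class ProtocolParseError(WardSimError):
    """A run-protocol file violates the schema; carries the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ProtocolInvariantError(WardSimError):
    """A run protocol violates a structural invariant (names which one)."""


class EmptySampleError(WardSimError):
    """An estimator was asked to average over zero observations."""


class UnknownPatientError(WardSimError):
    """A score function referenced a patient id absent from the protocol."""


class UndefinedScoreError(WardSimError):
    """A value model is undefined for this protocol (e.g. no nurses)."""


class DegenerateLegError(WardSimError):
    """Efficiency requested for a leg with zero travelled distance."""


class UndefinedQuotientError(WardSimError):
    """Fairness quotient requested with a zero efficiency score."""


class HeterogeneousRunsError(WardSimError):
    """ECQ evaluation was given protocols from different configurations."""


class PlanMismatchError(WardSimError):
    """A protocol does not belong to the floor plan it was plotted against."""
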