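"""Exception hierarchy for planning errors."""


class LifuPlanError(Exception):
    """Base class for all planning errors."""


class InvalidGeometryError(LifuPlanError):
    """Array geometry parameters are physically impossible."""


class PlanRangeError(LifuPlanError, ValueError):
    """A plan parameter lies outside its allowed range."""

    def __init__(self, parameter: str, value, bound_kind: str, bound):
        self.parameter = parameter
        self.value = value
        self.bound_kind = bound_kind
        self.bound = bound
        super().__init__(
            f"plan parameter {parameter!r} = {value} violates {bound_kind} bound {bound}"
        )


class InvalidTargetError(LifuPlanError):
    """Target is behind the array or otherwise unreachable geometrically."""


class UnreachableTargetError(LifuPlanError):
    """The acoustic path to the target is fully blocked (zero amplitude)."""


class OutOfGridError(LifuPlanError, KeyError):
    """Queried point lies outside a mapped candidate grid."""


class DegenerateNormalizationError(LifuPlanError):
    """Ray-bundle normalization references coincide (flat volume)."""


class NoValidPlacementError(LifuPlanError):
    """All candidate transducer placements are steering-invalid."""


class ThermalStabilityError(LifuPlanError):
    """Requested explicit time step violates the diffusion stability limit."""
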