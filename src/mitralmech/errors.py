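"""Exception hierarchy shared across the package."""


class MitralMechError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(MitralMechError, ValueError):
    """A material or configuration parameter violates its admissible domain."""


class InvalidDeformationError(MitralMechError, ValueError):
    """Deformation gradient with non-positive determinant (or other bad kinematics)."""


class ValidationError(MitralMechError, ValueError):
    """Structured input fails a shape/symmetry/consistency check."""


class EmptyRegionError(MitralMechError, ValueError):
    """A region average was requested over an empty selection."""


class NetworkSpecError(MitralMechError, ValueError):
    """Chordae-network specification is infeasible or inconsistent."""


class ScenarioError(MitralMechError, ValueError):
    """Unknown or malformed rupture-scenario request."""


class SingularityError(MitralMechError, RuntimeError):
    """Truss system is a mechanism: an under-constrained free node."""

    def __init__(self, node_id, message=None):
        self.node_id = node_id
        super().__init__(message or f"singular stiffness at free node {node_id!r}")


class ConvergenceError(MitralMechError, RuntimeError):
    """Newton iteration failed to converge; carries the residual history."""

    def __init__(self, message, residual_history=None):
        self.residual_history = list(residual_history or [])
        super().__init__(message)


class ClosureDetectionError(MitralMechError, ValueError):
    """No valve-closure zero crossing found in the mitral flow trace."""


class UndefinedQuantityError(MitralMechError, ZeroDivisionError):
    """A ratio (regurgitant fraction, efficiency, distribution) is undefined."""
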