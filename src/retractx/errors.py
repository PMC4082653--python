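"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`RetractxError`
so pipeline stages can catch and re-raise with stage context.
"""


class RetractxError(Exception):
    """Base class for all retractx errors."""


class GeometryError(RetractxError):
    """Degenerate or inconsistent geometric input (collinear points, non-unit normal...)."""


class ConfigurationError(RetractxError):
    """Invalid parameter combination (non-multiple element size, bad schema...)."""


class MeshError(RetractxError):
    """Meshing failed (empty mask, crack touching no element when required...)."""


class SizingError(ConfigurationError):
    """Grid too small to contain the requested phantom geometry."""


class SamplingError(RetractxError):
    """A stochastic sampling operation produced an empty/invalid result."""


class BoundsError(RetractxError):
    """A computed point left the image grid."""


class RegistrationError(RetractxError):
    """Point-set registration failed or did not reach its residual threshold."""


class AssemblyError(RetractxError):
    """Finite element assembly failed (non-positive Jacobian...)."""


class SolverError(RetractxError):
    """The reduced linear system is singular or the solve did not meet tolerance."""


class ConsistencyError(RetractxError):
    """A boundary condition refers to a DOF the discretization does not carry."""


class ConflictError(RetractxError):
    """Two sources prescribe incompatible values at the same node/side."""


class LocationError(RetractxError):
    """Point location in the (deformed) mesh failed."""


class PairingError(RetractxError):
    """Bead tables cannot be matched by id."""


class MetricError(RetractxError):
    """A metric was requested on degenerate input (empty point set...)."""
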