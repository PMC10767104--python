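"""Exception hierarchy for sutterbyflow."""


class SutterbyflowError(Exception):
    """Base class for all package-specific errors."""


class ClosedChannelError(SutterbyflowError):
    """The channel walls touch or cross at a requested station (h1 >= h2)."""


class DomainError(SutterbyflowError):
    """An evaluation point lies outside the channel cross-section [h1, h2]."""


class DegenerateSutterbyFactor(SutterbyflowError):
    """The effective-viscosity factor 1 - beta_F*(psi'')^2 vanishes on the mesh.

    The quasilinear stream-function equation divides by this factor when cast
    in explicit form, so a sign change makes the ODE singular.
    """


class NonConvergence(SutterbyflowError):
    """An iterative solver failed to reach its tolerance."""


class SingularBoundarySystem(SutterbyflowError):
    """The linear system fixing the integration constants is singular."""
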