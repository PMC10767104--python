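"""Channel geometry, dimensionless groups, and parameter validation.

The flow domain is a two-dimensional tapered channel whose walls deform as
travelling sine waves of period one in both the axial coordinate ``xi`` and
time ``t`` (wave frame, fully dimensionless)::

    h2(xi, t) =  1 + m*xi + b*sin(2*pi*(xi - t))            upper wall
    h1(xi, t) = -1 - m*xi - a*sin(2*pi*(xi - t) + omega)    lower wall

``m`` tapers the channel, ``a``/``b`` are the wall-wave amplitudes and
``omega`` the phase shift between the two walls (``omega = 0`` gives a
symmetric channel).  The local dimensionless flow rate is

    F(xi, t) = Theta + a*sin(2*pi*(xi - t) + omega) + b*sin(2*pi*(xi - t))

with ``Theta`` the mean flow rate.  The companion constant ``Q = F + d + 1``
mixes a dimensional half-width symbol into a dimensionless relation; it is
recorded here for completeness (with the half-width scaled to one it reads
``Q = F + 2``) but is never consumed by any solver.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields

from .errors import ClosedChannelError

__all__ = [
    "DimensionlessParams",
    "ChannelGeometry",
    "CrossSection",
    "ValidationReport",
    "wall_positions",
    "flow_rate",
    "cross_section",
    "validate_params",
]


@dataclass(frozen=True)
class DimensionlessParams:
    """Dimensionless groups governing the reduced cross-channel system.

    Defaults are the baseline operating point used throughout the profile and
    sweep studies.  ``beta_F`` defaults to 0.1 so that the Sutterby
    effective-viscosity factor ``1 - beta_F*(psi'')^2`` remains positive over
    the channel at the baseline flow rate; see docs/methods.md.

    Attributes
    ----------
    beta_F : Sutterby fluid parameter (0 recovers the Newtonian limit).
    M : Hartmann number (magnetic field strength).
    beta_e, beta_i : Hall and ion-slip parameters of the Lorentz force.
    G_R, G_C : thermal and solutal (nanoparticle) Grashof numbers.
    Pr : Prandtl number.
    N_T, N_B : thermophoresis and Brownian-motion parameters.
    E_C : Eckert number (viscous + Joule dissipation strength).
    Sc : Schmidt number.
    K_R : first-order chemical-reaction parameter.
    Ra : Reynolds number (enters only the axial body force).
    Fr : Froude number.
    Lambda : channel inclination angle, radians.
    """

    beta_F: float = 0.1
    M: float = 2.0
    beta_e: float = 0.5
    beta_i: float = 0.4
    G_R: float = 0.2
    G_C: float = 0.2
    Pr: float = 21.0
    N_T: float = 1.0
    N_B: float = 0.5
    E_C: float = 0.1
    Sc: float = 0.6
    K_R: float = 0.5
    Ra: float = 0.5
    Fr: float = 0.5
    Lambda: float = math.pi / 2

    @property
    def hall_denominator(self) -> float:
        """D = (1 + beta_e*beta_i)^2 + beta_e^2, positive for all real inputs."""
        return (1.0 + self.beta_e * self.beta_i) ** 2 + self.beta_e**2

    @property
    def lorentz_coefficient(self) -> float:
        """kappa = M^2 (1 + beta_e*beta_i) / D, the magnetic damping factor."""
        return self.M**2 * (1.0 + self.beta_e * self.beta_i) / self.hall_denominator

    @property
    def thermophoresis_ratio(self) -> float:
        """N_T / N_B, with the convention that zero thermophoresis decouples
        the species equation from temperature even when N_B is also zero."""
        return 0.0 if self.N_T == 0 else self.N_T / self.N_B

    def replace(self, **changes) -> "DimensionlessParams":
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        values.update(changes)
        return DimensionlessParams(**values)


@dataclass(frozen=True)
class ChannelGeometry:
    """Wall-wave amplitudes, taper, phase shift and mean flow rate."""

    a: float = 0.3
    b: float = 0.3
    m: float = 0.2
    omega: float = math.pi / 2
    Theta: float = 1.4

    def __post_init__(self):
        if not (0.0 <= self.omega <= math.pi):
            warnings.warn(
                f"phase difference omega={self.omega} outside the usual range "
                "[0, pi]; the wall shapes remain well defined",
                stacklevel=3,
            )


@dataclass(frozen=True)
class CrossSection:
    """A frozen channel cross-section: station, walls and local flow rate."""

    xi: float
    t: float
    h1: float
    h2: float
    F: float

    @property
    def width(self) -> float:
        return self.h2 - self.h1

    @property
    def centre(self) -> float:
        return 0.5 * (self.h1 + self.h2)


def wall_positions(xi: float, t: float, geom: ChannelGeometry) -> tuple[float, float]:
    """Lower and upper wall positions (h1, h2) at station ``xi`` and time ``t``.

    Raises
    ------
    ClosedChannelError
        If the walls touch or cross (h1 >= h2); the parameters are then
        outside the modelling range of an open peristaltic channel.
    """
    phase = 2.0 * math.pi * (xi - t)
    h2 = 1.0 + geom.m * xi + geom.b * math.sin(phase)
    h1 = -1.0 - geom.m * xi - geom.a * math.sin(phase + geom.omega)
    if h1 >= h2:
        raise ClosedChannelError(
            f"channel closed at xi={xi}, t={t}: h1={h1:.6g} >= h2={h2:.6g}"
        )
    return h1, h2


def flow_rate(xi: float, t: float, geom: ChannelGeometry) -> float:
    """Local dimensionless flow rate F(xi, t)."""
    phase = 2.0 * math.pi * (xi - t)
    return geom.Theta + geom.a * math.sin(phase + geom.omega) + geom.b * math.sin(phase)


def cross_section(xi: float, t: float, geom: ChannelGeometry) -> CrossSection:
    """Bundle walls and flow rate at (xi, t) into a :class:`CrossSection`."""
    h1, h2 = wall_positions(xi, t, geom)
    return CrossSection(xi=xi, t=t, h1=h1, h2=h2, F=flow_rate(xi, t, geom))


@dataclass
class ValidationReport:
    """Report-style outcome of :func:`validate_params`."""

    violations: list = field(default_factory=list)
    hall_denominator: float = 1.0

    @property
    def valid(self) -> bool:
        return not self.violations


def validate_params(p: DimensionlessParams) -> ValidationReport:
    """Check the physical invariants of a parameter set without raising.

    The species equation divides by ``N_B`` and the energy equation by ``Pr``,
    hence the strict positivity requirements there.
    """
    report = ValidationReport(hall_denominator=p.hall_denominator)
    checks = [
        (p.Pr > 0, f"Pr must be positive (energy equation divides by Pr), got {p.Pr}"),
        (p.N_B > 0, f"N_B must be positive (species equation divides by N_B), got {p.N_B}"),
        (p.Sc >= 0, f"Sc must be non-negative, got {p.Sc}"),
        (p.K_R >= 0, f"K_R must be non-negative, got {p.K_R}"),
        (p.Fr > 0, f"Fr must be positive (body force divides by Fr), got {p.Fr}"),
        (p.M >= 0, f"M must be non-negative, got {p.M}"),
        (p.hall_denominator > 0, "Hall/ion-slip denominator D must be positive"),
    ]
    for ok, message in checks:
        if not ok:
            report.violations.append(message)
    return report
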