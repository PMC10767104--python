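"""Second-order homotopy-perturbation solver for the reduced channel system.

Under the long-wavelength, low-Reynolds (lubrication) reduction the coupled
transport of a magnetized Sutterby nanofluid across one channel section
becomes a boundary-value problem in the cross-channel coordinate ``eta``
alone, for the stream function ``psi``, temperature ``theta`` and
nanoparticle concentration ``phi``::

    psi'''' (1 - beta_F psi''^2) - kappa psi'' + G_R theta' + G_C phi' = 0
    theta''/Pr + N_T theta'^2 + N_B theta' phi'
        + E_C M^2/D psi'^2 + E_C psi''^2 (1 - beta_F psi''^2) = 0
    phi'' + (N_T/N_B) theta'' - Sc K_R phi = 0

with ``kappa = M^2 (1 + beta_e beta_i)/D`` and
``D = (1 + beta_e beta_i)^2 + beta_e^2`` the Hall/ion-slip factor, and the
eight boundary values

    psi(h1) = -F/2,  psi(h2) = F/2,  psi'(h1) = psi'(h2) = 0,
    theta(h1) = 0,   theta(h2) = 1,  phi(h1) = 0,  phi(h2) = 1.

The homotopy perturbation method (HPM) embeds this system in a family
indexed by ``p`` in [0, 1] whose linear part is the bare highest derivative;
expanding each unknown as ``psi = psi0 + p psi1 + p^2 psi2`` (and likewise
for theta and phi) yields a cascade of *linear* constant-left-hand-side
problems

    order 0:  psi0'''' = 0,  theta0'' = 0,  phi0'' = 0
    order k:  the k-th power of p, with all lower orders known,

each of which is solved exactly by repeated antidifferentiation of a
polynomial forcing plus a small linear solve for the integration constants.
Everything in this module is exact polynomial algebra on the coefficient
representation -- no collocation, quadrature, or truncation enters the
cascade.  With the default truncation at second order the assembled stream
function is a degree <= 9 polynomial and the temperature degree <= 8.

Two faithfulness notes.  First, the homotopy moves the energy equation's
second derivative from ``theta''`` (linear part) to ``theta''/Pr`` (full
operator), so the linear portion of the cascade contracts by a factor
``(1 - 1/Pr)`` per order: at large Prandtl number the second-order
truncation is far from converged for the temperature field, which the
residual diagnostics attached to every solution make visible.  Second, the
stream-function equation is used in the form printed above, which is the
lubrication momentum equation after a single ``eta`` differentiation
*without* the chain-rule term ``-2 beta_F psi'' psi''' (psi''')`` that
strict differentiation of the pressure-gradient relation would add; the
numerical cross-check in :mod:`sutterbyflow.oracle` treats the equations in
exactly the same form, so their comparison isolates truncation error only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numpy.polynomial import Polynomial

from .errors import SingularBoundarySystem
from .geometry import ChannelGeometry, CrossSection, DimensionlessParams, cross_section

__all__ = [
    "HPMConfig",
    "HPMSolution",
    "solve",
    "solve_order0",
    "build_rhs_order1",
    "build_rhs_order2",
    "solve_linear_poly_bvp",
]

#: exact zero polynomial, reused as a forcing at order zero
_ZERO = Polynomial([0.0])


@dataclass(frozen=True)
class HPMConfig:
    """Truncation order, boundary-condition allocation and diagnostics grid.

    ``bc_allocation`` decides which cascade order carries the inhomogeneous
    boundary data.  ``full_at_zeroth`` (default, and the only scheme under
    which the assembled sum satisfies the boundary conditions identically at
    every truncation order) gives order zero the full data and all higher
    orders homogeneous conditions.  ``split`` shares the data equally across
    the ``order + 1`` retained orders; it exists for sensitivity studies of
    the boundary-condition convention and is not recommended for production
    use.
    """

    order: int = 2
    bc_allocation: Literal["full_at_zeroth", "split"] = "full_at_zeroth"
    residual_grid_size: int = 201

    def __post_init__(self):
        if self.order not in (0, 1, 2):
            raise ValueError(f"HPM truncation order must be 0, 1 or 2, got {self.order}")
        if self.bc_allocation not in ("full_at_zeroth", "split"):
            raise ValueError(f"unknown bc_allocation {self.bc_allocation!r}")
        if self.residual_grid_size < 2:
            raise ValueError("residual_grid_size must be at least 2")


@dataclass
class HPMSolution:
    """Per-order and assembled polynomial solution of one cross-section.

    ``psi``, ``theta`` and ``phi`` are the order sums evaluated at embedding
    parameter p = 1.  ``residuals`` holds the max-norm residuals of the three
    governing equations on a uniform grid over [h1, h2]; for the momentum and
    species equations these measure pure cascade truncation, while the energy
    residual additionally reflects the slow (1 - 1/Pr) contraction discussed
    in the module docstring.
    """

    params: DimensionlessParams
    section: CrossSection
    config: HPMConfig
    psi_orders: list[Polynomial] = field(default_factory=list)
    theta_orders: list[Polynomial] = field(default_factory=list)
    phi_orders: list[Polynomial] = field(default_factory=list)
    residuals: dict = field(default_factory=dict)

    @property
    def psi(self) -> Polynomial:
        return sum(self.psi_orders[1:], self.psi_orders[0])

    @property
    def theta(self) -> Polynomial:
        return sum(self.theta_orders[1:], self.theta_orders[0])

    @property
    def phi(self) -> Polynomial:
        return sum(self.phi_orders[1:], self.phi_orders[0])

    @property
    def u(self) -> Polynomial:
        """Axial velocity u = d(psi)/d(eta)."""
        return self.psi.deriv()


def solve_linear_poly_bvp(
    order: int,
    rhs: Polynomial,
    h1: float,
    h2: float,
    bc: tuple[float, ...],
) -> Polynomial:
    """Solve u^(order) = rhs exactly with boundary data at the two walls.

    Parameters
    ----------
    order : 2 or 4.  Fourth order is the stream-function type with boundary
        data ``(u(h1), u(h2), u'(h1), u'(h2))``; second order is the
        temperature/concentration type with data ``(u(h1), u(h2))``.
    rhs : polynomial forcing.
    bc : boundary values, length matching ``order``.

    The particular solution is the ``order``-fold antiderivative of ``rhs``
    (integration constants zero); the complementary polynomial of degree
    ``order - 1`` is fixed by a dense solve of the small boundary system.
    """
    if order not in (2, 4):
        raise ValueError(f"derivative order must be 2 or 4, got {order}")
    if len(bc) != order:
        raise ValueError(f"expected {order} boundary values, got {len(bc)}")
    part = rhs.integ(order)
    if order == 4:
        dpart = part.deriv()
        A = np.array(
            [
                [1.0, h1, h1**2, h1**3],
                [1.0, h2, h2**2, h2**3],
                [0.0, 1.0, 2 * h1, 3 * h1**2],
                [0.0, 1.0, 2 * h2, 3 * h2**2],
            ]
        )
        b = np.array([bc[0] - part(h1), bc[1] - part(h2), bc[2] - dpart(h1), bc[3] - dpart(h2)])
    else:
        A = np.array([[1.0, h1], [1.0, h2]])
        b = np.array([bc[0] - part(h1), bc[1] - part(h2)])
    try:
        const = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:  # h1 == h2, excluded upstream
        raise SingularBoundarySystem(f"degenerate boundary system: {exc}") from exc
    return part + Polynomial(const)


def _bc_sets(section: CrossSection, config: HPMConfig, order_index: int):
    """Boundary data for cascade order ``order_index`` under the allocation."""
    if config.bc_allocation == "full_at_zeroth":
        weight = 1.0 if order_index == 0 else 0.0
    else:  # split equally across retained orders
        weight = 1.0 / (config.order + 1)
    F = section.F
    psi_bc = (-weight * F / 2.0, weight * F / 2.0, 0.0, 0.0)
    ramp_bc = (0.0, weight * 1.0)
    return psi_bc, ramp_bc


def solve_order0(
    section: CrossSection, config: HPMConfig | None = None
) -> tuple[Polynomial, Polynomial, Polynomial]:
    """Zeroth-order cascade: cubic stream function and linear ramps.

    psi0 is the unique cubic satisfying the four stream-function boundary
    values; theta0 and phi0 are the linear ramps from 0 at h1 to 1 at h2
    (under the default allocation).
    """
    config = config or HPMConfig()
    psi_bc, ramp_bc = _bc_sets(section, config, 0)
    psi0 = solve_linear_poly_bvp(4, _ZERO, section.h1, section.h2, psi_bc)
    theta0 = solve_linear_poly_bvp(2, _ZERO, section.h1, section.h2, ramp_bc)
    phi0 = solve_linear_poly_bvp(2, _ZERO, section.h1, section.h2, ramp_bc)
    return psi0, theta0, phi0


def build_rhs_order1(
    psi0: Polynomial,
    theta0: Polynomial,
    phi0: Polynomial,
    p: DimensionlessParams,
) -> tuple[Polynomial, Polynomial, Polynomial]:
    """Forcing polynomials for the first-order cascade problems.

    Obtained by moving every known (order-0) term of the first power of the
    embedding parameter across the equals sign.  The Hall/ion-slip factors in
    the higher-order momentum and energy terms are read with the ion-slip
    parameter throughout (the typeset first/second-order equations drift
    between subscripted beta symbols that are all defined as beta_i).
    """
    D = p.hall_denominator
    kappa = p.lorentz_coefficient
    d2psi0 = psi0.deriv(2)
    d4psi0 = psi0.deriv(4)
    dtheta0 = theta0.deriv()
    rhs_psi1 = (
        p.beta_F * d4psi0 * d2psi0**2
        - p.G_R * dtheta0
        + kappa * d2psi0
        - p.G_C * phi0.deriv()
    )
    rhs_theta1 = (
        theta0.deriv(2) * (1.0 - 1.0 / p.Pr)
        - p.N_T * dtheta0**2
        - p.N_B * dtheta0 * phi0.deriv()
        - p.E_C * d2psi0**2 * (1.0 - p.beta_F * d2psi0**2)
        - p.E_C * p.M**2 / D * psi0.deriv() ** 2
    )
    rhs_phi1 = -p.thermophoresis_ratio * theta0.deriv(2) + p.Sc * p.K_R * phi0
    return rhs_psi1, rhs_theta1, rhs_phi1


def build_rhs_order2(
    psi0: Polynomial,
    theta0: Polynomial,
    phi0: Polynomial,
    psi1: Polynomial,
    theta1: Polynomial,
    phi1: Polynomial,
    p: DimensionlessParams,
) -> tuple[Polynomial, Polynomial, Polynomial]:
    """Forcing polynomials for the second-order cascade problems.

    These carry the quadratic cross terms between orders 0 and 1 of the
    Sutterby viscosity factor and of both dissipation terms.
    """
    D = p.hall_denominator
    kappa = p.lorentz_coefficient
    d2psi0, d2psi1 = psi0.deriv(2), psi1.deriv(2)
    d4psi0, d4psi1 = psi0.deriv(4), psi1.deriv(4)
    dtheta0, dtheta1 = theta0.deriv(), theta1.deriv()
    sutterby0 = 1.0 - p.beta_F * d2psi0**2
    rhs_psi2 = (
        p.beta_F * d4psi1 * d2psi0**2
        + 2.0 * p.beta_F * d4psi0 * d2psi0 * d2psi1
        - p.G_R * dtheta1
        + kappa * d2psi1
        - p.G_C * phi1.deriv()
    )
    rhs_theta2 = (
        theta1.deriv(2) * (1.0 - 1.0 / p.Pr)
        - 2.0 * p.N_T * dtheta0 * dtheta1
        - p.N_B * dtheta0 * phi1.deriv()
        - p.N_B * dtheta1 * phi0.deriv()
        + 2.0 * p.E_C * p.beta_F * d2psi0**3 * d2psi1
        - 2.0 * p.E_C * p.M**2 / D * psi0.deriv() * psi1.deriv()
        - 2.0 * p.E_C * d2psi0 * d2psi1 * sutterby0
    )
    rhs_phi2 = -p.thermophoresis_ratio * theta1.deriv(2) + p.Sc * p.K_R * phi1
    return rhs_psi2, rhs_theta2, rhs_phi2


def _residuals(
    params: DimensionlessParams,
    section: CrossSection,
    psi: Polynomial,
    theta: Polynomial,
    phi: Polynomial,
    n_grid: int,
) -> dict:
    """Max-norm residuals of the three governing equations on a uniform grid."""
    eta = np.linspace(section.h1, section.h2, n_grid)
    D = params.hall_denominator
    kappa = params.lorentz_coefficient
    dpsi, d2psi = psi.deriv()(eta), psi.deriv(2)(eta)
    d3psi, d4psi = psi.deriv(3)(eta), psi.deriv(4)(eta)
    dtheta, d2theta = theta.deriv()(eta), theta.deriv(2)(eta)
    dphi, d2phi = phi.deriv()(eta), phi.deriv(2)(eta)
    del d3psi  # the momentum residual uses the once-differentiated form
    sutterby = 1.0 - params.beta_F * d2psi**2
    momentum = (
        d4psi * sutterby - kappa * d2psi + params.G_R * dtheta + params.G_C * dphi
    )
    energy = (
        d2theta / params.Pr
        + params.N_T * dtheta**2
        + params.N_B * dtheta * dphi
        + params.E_C * params.M**2 / D * dpsi**2
        + params.E_C * d2psi**2 * sutterby
    )
    species = (d2phi + params.thermophoresis_ratio * d2theta
               - params.Sc * params.K_R * phi(eta))
    return {
        "momentum": float(np.max(np.abs(momentum))),
        "energy": float(np.max(np.abs(energy))),
        "species": float(np.max(np.abs(species))),
    }


def solve(
    params: DimensionlessParams,
    section: CrossSection | None = None,
    config: HPMConfig | None = None,
    *,
    geom: ChannelGeometry | None = None,
    xi: float | None = None,
    t: float | None = None,
) -> HPMSolution:
    """Run the HPM cascade at one cross-section and assemble the solution.

    Either pass a prebuilt ``section`` or a ``geom`` with station ``xi`` and
    time ``t``.  Within every order the temperature problem is solved first,
    then concentration (whose forcing consumes temperature curvature), then
    the stream function (whose forcing consumes both gradients).
    """
    if section is None:
        if geom is None or xi is None or t is None:
            raise ValueError("pass either section= or all of geom=, xi=, t=")
        section = cross_section(xi, t, geom)
    config = config or HPMConfig()

    psi0, theta0, phi0 = solve_order0(section, config)
    sol = HPMSolution(params=params, section=section, config=config,
                      psi_orders=[psi0], theta_orders=[theta0], phi_orders=[phi0])

    h1, h2 = section.h1, section.h2
    if config.order >= 1:
        psi_bc, ramp_bc = _bc_sets(section, config, 1)
        rhs_psi1, rhs_theta1, rhs_phi1 = build_rhs_order1(psi0, theta0, phi0, params)
        theta1 = solve_linear_poly_bvp(2, rhs_theta1, h1, h2, ramp_bc)
        phi1 = solve_linear_poly_bvp(2, rhs_phi1, h1, h2, ramp_bc)
        psi1 = solve_linear_poly_bvp(4, rhs_psi1, h1, h2, psi_bc)
        sol.psi_orders.append(psi1)
        sol.theta_orders.append(theta1)
        sol.phi_orders.append(phi1)
    if config.order >= 2:
        psi_bc, ramp_bc = _bc_sets(section, config, 2)
        rhs_psi2, rhs_theta2, rhs_phi2 = build_rhs_order2(
            psi0, theta0, phi0, psi1, theta1, phi1, params
        )
        theta2 = solve_linear_poly_bvp(2, rhs_theta2, h1, h2, ramp_bc)
        phi2 = solve_linear_poly_bvp(2, rhs_phi2, h1, h2, ramp_bc)
        psi2 = solve_linear_poly_bvp(4, rhs_psi2, h1, h2, psi_bc)
        sol.psi_orders.append(psi2)
        sol.theta_orders.append(theta2)
        sol.phi_orders.append(phi2)

    sol.residuals = _residuals(
        params, section, sol.psi, sol.theta, sol.phi, config.residual_grid_size
    )
    return sol
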