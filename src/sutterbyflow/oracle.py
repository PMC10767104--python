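"""Independent numerical solution of the cross-channel system.

The same three equations the HPM cascade truncates are solved here without
any perturbation expansion, as a first-order system of eight state
components with collocation (:func:`scipy.integrate.solve_bvp`).  Because
both routes treat the equations in the identical as-printed form, the
discrepancy between them measures cascade truncation only.

The stream-function equation is quasilinear: casting it in explicit form
divides by the Sutterby factor ``1 - beta_F*(psi'')^2``, so parameter sets
for which that factor crosses zero inside the channel are outside the
oracle's range and raise :class:`~sutterbyflow.errors.DegenerateSutterbyFactor`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_bvp

from .errors import DegenerateSutterbyFactor, NonConvergence
from .geometry import CrossSection, DimensionlessParams
from .hpm import HPMConfig, HPMSolution, solve_order0

__all__ = ["GridSolution", "DiscrepancyReport", "solve_numeric", "compare"]

_FACTOR_FLOOR = 1e-8


@dataclass
class GridSolution:
    """Collocation solution sampled on the solver's adaptive mesh."""

    eta_nodes: np.ndarray
    psi: np.ndarray
    u: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    converged: bool
    n_iterations: int
    max_residual: float
    interpolant: object  # dense C1 interpolant from solve_bvp

    def sample(self, eta: np.ndarray) -> dict:
        y = self.interpolant(eta)
        return {"psi": y[0], "u": y[1], "theta": y[4], "phi": y[6]}


def solve_numeric(
    params: DimensionlessParams,
    section: CrossSection,
    tol: float = 1e-8,
    mesh_size: int = 101,
    max_nodes: int = 100_000,
) -> GridSolution:
    """Solve the coupled boundary-value problem by adaptive collocation.

    State vector: (psi, psi', psi'', psi''', theta, theta', phi, phi').
    Initial guess: the zeroth-order HPM closed form (cubic stream function
    and linear ramps), which always exists.

    Raises
    ------
    DegenerateSutterbyFactor
        If ``1 - beta_F*(psi'')^2`` changes sign or falls below 1e-8 in
        magnitude on the (initial or converged) mesh.
    NonConvergence
        If the collocation solver stops without reaching its tolerance.
    """
    D = params.hall_denominator
    kappa = params.lorentz_coefficient
    bF, GR, GC = params.beta_F, params.G_R, params.G_C
    Pr, NT, NB, EC, M2 = params.Pr, params.N_T, params.N_B, params.E_C, params.M**2
    nt_nb = params.thermophoresis_ratio
    ScKR = params.Sc * params.K_R
    F = section.F

    def rhs(eta, y):
        psi, dpsi, d2psi, d3psi, theta, dtheta, phi, dphi = y
        factor = 1.0 - bF * d2psi**2
        d4psi = (kappa * d2psi - GR * dtheta - GC * dphi) / factor
        d2theta = -Pr * (
            NT * dtheta**2
            + NB * dtheta * dphi
            + EC * M2 / D * dpsi**2
            + EC * d2psi**2 * factor
        )
        d2phi = -nt_nb * d2theta + ScKR * phi
        return np.vstack([dpsi, d2psi, d3psi, d4psi, dtheta, d2theta, dphi, d2phi])

    def bc(ya, yb):
        return np.array(
            [ya[0] + F / 2, yb[0] - F / 2, ya[1], yb[1], ya[4], yb[4] - 1.0, ya[6], yb[6] - 1.0]
        )

    psi0, theta0, phi0 = solve_order0(section, HPMConfig(order=0))
    x = np.linspace(section.h1, section.h2, mesh_size)
    y0 = np.vstack(
        [
            psi0(x), psi0.deriv()(x), psi0.deriv(2)(x), psi0.deriv(3)(x),
            theta0(x), theta0.deriv()(x), phi0(x), phi0.deriv()(x),
        ]
    )

    guess_factor = 1.0 - bF * y0[2] ** 2
    if np.min(np.abs(guess_factor)) < _FACTOR_FLOOR or np.min(guess_factor) < 0 < np.max(guess_factor):
        raise DegenerateSutterbyFactor(
            "Sutterby factor 1 - beta_F*(psi'')^2 crosses zero on the initial "
            f"guess (min {guess_factor.min():.3g}); the explicit-form ODE is singular"
        )

    result = solve_bvp(rhs, bc, x, y0, tol=tol, max_nodes=max_nodes)
    if result.status != 0:
        raise NonConvergence(
            f"collocation failed (status {result.status}: {result.message}); "
            f"mesh size {result.x.size}, max residual {result.rms_residuals.max():.3g}"
        )
    factor = 1.0 - bF * result.y[2] ** 2
    if np.min(np.abs(factor)) < _FACTOR_FLOOR or factor.min() < 0 < factor.max():
        raise DegenerateSutterbyFactor(
            f"Sutterby factor reaches {factor.min():.3g} on the converged mesh"
        )
    return GridSolution(
        eta_nodes=result.x,
        psi=result.y[0],
        u=result.y[1],
        theta=result.y[4],
        phi=result.y[6],
        converged=True,
        n_iterations=result.niter,
        max_residual=float(result.rms_residuals.max()),
        interpolant=result.sol,
    )


@dataclass
class DiscrepancyReport:
    """Max and L2 discrepancies between HPM and collocation on the oracle mesh."""

    max_u: float
    max_theta: float
    max_phi: float
    l2_u: float
    l2_theta: float
    l2_phi: float
    n_nodes: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("max_u", "max_theta", "max_phi", "l2_u", "l2_theta", "l2_phi", "n_nodes")}


def compare(hpm_sol: HPMSolution, num: GridSolution) -> DiscrepancyReport:
    """Discrepancies of u, theta, phi between the two solution routes."""
    eta = num.eta_nodes
    width = eta[-1] - eta[0]

    def norms(a, b):
        diff = a - b
        l2 = float(np.sqrt(np.trapezoid(diff**2, eta) / width))
        return float(np.max(np.abs(diff))), l2

    max_u, l2_u = norms(hpm_sol.u(eta), num.u)
    max_th, l2_th = norms(hpm_sol.theta(eta), num.theta)
    max_ph, l2_ph = norms(hpm_sol.phi(eta), num.phi)
    return DiscrepancyReport(
        max_u=max_u, max_theta=max_th, max_phi=max_ph,
        l2_u=l2_u, l2_theta=l2_th, l2_phi=l2_ph, n_nodes=eta.size,
    )
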