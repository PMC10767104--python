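"""Derived quantities: velocity, shear stress, pressure, heat transfer.

All observables are evaluated from the assembled HPM polynomials, so each is
exact given the cascade solution.  Quantities that involve the axial
direction (pressure rise per wavelength, streamline and isotherm grids)
re-solve the cascade section by section.

Conventions that the source formulation leaves open are explicit keyword
selectors here:

* the pressure gradient depends on the cross-channel coordinate; the
  evaluation point defaults to mid-channel (``eta_eval="centre"``) and may
  be a wall or the cross-sectional average;
* the heat-transfer coefficient is ``Z = (dh2/dxi) * theta'`` at the upper
  wall, and the Nusselt number is the signed wall temperature gradient
  ``theta'(h2)``; both accept ``wall``/``sign`` selectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import math

import numpy as np
from numpy.polynomial.legendre import leggauss

from .errors import DomainError
from .geometry import ChannelGeometry, CrossSection, DimensionlessParams, cross_section
from .hpm import HPMConfig, HPMSolution, solve

__all__ = [
    "ProfileGrid",
    "PressureSweep",
    "axial_velocity",
    "shear_stress",
    "pressure_gradient",
    "pressure_rise",
    "heat_transfer_coefficient",
    "nusselt",
    "stream_grid",
    "isotherm_grid",
]

_EDGE_TOL = 1e-12


def _check_domain(sol: HPMSolution, eta) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    h1, h2 = sol.section.h1, sol.section.h2
    if np.any(eta < h1 - _EDGE_TOL) or np.any(eta > h2 + _EDGE_TOL):
        raise DomainError(
            f"eta outside the channel [{h1:.6g}, {h2:.6g}]"
        )
    return eta


def axial_velocity(sol: HPMSolution, eta):
    """u = d(psi)/d(eta) at one or more cross-channel positions."""
    eta = _check_domain(sol, eta)
    return sol.psi.deriv()(eta)


def shear_stress(sol: HPMSolution, eta):
    """Sutterby shear stress tau = [1 - beta_F*(psi'')^2] * psi''."""
    eta = _check_domain(sol, eta)
    d2 = sol.psi.deriv(2)(eta)
    return (1.0 - sol.params.beta_F * d2**2) * d2


def _resolve_eta_eval(section: CrossSection, eta_eval) -> float | None:
    if eta_eval is None or eta_eval == "centre":
        return section.centre
    if eta_eval == "h1":
        return section.h1
    if eta_eval == "h2":
        return section.h2
    if eta_eval == "average":
        return None  # handled by the caller via quadrature
    return float(eta_eval)


def pressure_gradient(
    params: DimensionlessParams,
    section: CrossSection,
    sol: HPMSolution | None = None,
    eta_eval: float | Literal["centre", "h1", "h2", "average"] = "centre",
    config: HPMConfig | None = None,
) -> float:
    """Axial pressure gradient dp/dxi at the requested evaluation point.

    dp/dxi = psi'''(1 - beta_F psi''^2) - kappa psi' + G_R theta + G_C phi
             + (Ra/Fr) sin(Lambda)

    The expression retains an eta dependence in the lubrication limit;
    ``eta_eval`` selects where it is read (default: channel centre).
    """
    if sol is None:
        sol = solve(params, section, config)
    psi, theta, phi = sol.psi, sol.theta, sol.phi
    kappa = params.lorentz_coefficient
    body = params.Ra / params.Fr * math.sin(params.Lambda)

    def at(eta):
        d2 = psi.deriv(2)(eta)
        return (
            psi.deriv(3)(eta) * (1.0 - params.beta_F * d2**2)
            - kappa * psi.deriv()(eta)
            + params.G_R * theta(eta)
            + params.G_C * phi(eta)
            + body
        )

    point = _resolve_eta_eval(section, eta_eval)
    if point is None:  # cross-sectional average by Gauss-Legendre
        x, w = leggauss(32)
        half = 0.5 * (section.h2 - section.h1)
        nodes = section.centre + half * x
        return float(np.sum(w * at(nodes)) * half / (section.h2 - section.h1))
    eta = _check_domain(sol, point)
    return float(at(eta))


def pressure_rise(
    params: DimensionlessParams,
    geom: ChannelGeometry,
    t: float,
    quadrature_n: int = 64,
    eta_eval="centre",
    config: HPMConfig | None = None,
) -> float:
    """Pressure rise per wavelength: integral of dp/dxi over xi in [0, 1].

    The cascade is re-solved at every Gauss-Legendre node's cross-section;
    the integrand is smooth in xi for an open channel, so 64 nodes resolve
    it far below the truncation level of the solution itself.
    """
    x, w = leggauss(quadrature_n)
    xi_nodes = 0.5 * (x + 1.0)
    weights = 0.5 * w
    total = 0.0
    for xi, wi in zip(xi_nodes, weights):
        section = cross_section(xi, t, geom)
        total += wi * pressure_gradient(params, section, eta_eval=eta_eval, config=config)
    return float(total)


def heat_transfer_coefficient(
    params: DimensionlessParams,
    geom: ChannelGeometry,
    xi: float,
    t: float,
    wall: Literal["h1", "h2"] = "h2",
    config: HPMConfig | None = None,
    sol: HPMSolution | None = None,
) -> float:
    """Heat-transfer coefficient Z = (dh/dxi) * theta' at the selected wall.

    The wall-slope factor for the upper wall is
    ``dh2/dxi = m + 2*pi*b*cos(2*pi*(xi - t))`` and for the lower wall
    ``dh1/dxi = -m - 2*pi*a*cos(2*pi*(xi - t) + omega)``.
    """
    section = sol.section if sol is not None else cross_section(xi, t, geom)
    if sol is None:
        sol = solve(params, section, config)
    phase = 2.0 * math.pi * (xi - t)
    if wall == "h2":
        slope = geom.m + 2.0 * math.pi * geom.b * math.cos(phase)
        return float(slope * sol.theta.deriv()(section.h2))
    slope = -geom.m - 2.0 * math.pi * geom.a * math.cos(phase + geom.omega)
    return float(slope * sol.theta.deriv()(section.h1))


def nusselt(
    params: DimensionlessParams,
    geom: ChannelGeometry,
    xi: float,
    t: float,
    wall: Literal["h1", "h2"] = "h2",
    sign: int = 1,
    config: HPMConfig | None = None,
    sol: HPMSolution | None = None,
) -> float:
    """Nusselt number: the (signed) wall temperature gradient theta'(wall).

    Default convention: ``+theta'`` at the upper wall h2.  ``sign=-1`` and
    ``wall="h1"`` expose the alternative conventions.
    """
    section = sol.section if sol is not None else cross_section(xi, t, geom)
    if sol is None:
        sol = solve(params, section, config)
    eta_w = section.h2 if wall == "h2" else section.h1
    return float(sign * sol.theta.deriv()(eta_w))


@dataclass
class ProfileGrid:
    """A quantity sampled on an (xi, eta) mesh, NaN-masked outside the channel."""

    quantity: str
    xi: np.ndarray            # (n_xi,)
    eta: np.ndarray           # (n_eta,) global eta axis
    values: np.ndarray        # (n_xi, n_eta), NaN outside [h1(xi), h2(xi)]
    h1: np.ndarray            # (n_xi,)
    h2: np.ndarray            # (n_xi,)
    params: DimensionlessParams | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class PressureSweep:
    """Pressure rise per wavelength over a sweep of mean flow rates."""

    Theta: np.ndarray
    delta_p: np.ndarray
    params: DimensionlessParams | None = None
    meta: dict = field(default_factory=dict)


def _field_grid(
    params: DimensionlessParams,
    geom: ChannelGeometry,
    t: float,
    xi_range: tuple[float, float],
    n_xi: int,
    n_eta: int,
    picker,
    quantity: str,
    config: HPMConfig | None = None,
) -> ProfileGrid:
    xi_vals = np.linspace(xi_range[0], xi_range[1], n_xi)
    sections = [cross_section(xi, t, geom) for xi in xi_vals]
    h1s = np.array([s.h1 for s in sections])
    h2s = np.array([s.h2 for s in sections])
    eta = np.linspace(h1s.min(), h2s.max(), n_eta)
    values = np.full((n_xi, n_eta), np.nan)
    for i, section in enumerate(sections):
        sol = solve(params, section, config)
        poly = picker(sol)
        inside = (eta >= section.h1) & (eta <= section.h2)
        values[i, inside] = poly(eta[inside])
    return ProfileGrid(
        quantity=quantity, xi=xi_vals, eta=eta, values=values,
        h1=h1s, h2=h2s, params=params, meta={"t": t, "geom": geom},
    )


def stream_grid(
    params: DimensionlessParams,
    geom: ChannelGeometry,
    t: float,
    xi_range: tuple[float, float] = (0.0, 1.0),
    n_xi: int = 41,
    n_eta: int = 81,
    config: HPMConfig | None = None,
) -> ProfileGrid:
    """Stream-function values on an (xi, eta) mesh; level sets are streamlines."""
    return _field_grid(params, geom, t, xi_range, n_xi, n_eta,
                       lambda s: s.psi, "psi", config)


def isotherm_grid(
    params: DimensionlessParams,
    geom: ChannelGeometry,
    t: float,
    xi_range: tuple[float, float] = (0.0, 1.0),
    n_xi: int = 41,
    n_eta: int = 81,
    config: HPMConfig | None = None,
) -> ProfileGrid:
    """Temperature values on an (xi, eta) mesh; level sets are isotherms."""
    return _field_grid(params, geom, t, xi_range, n_xi, n_eta,
                       lambda s: s.theta, "theta", config)
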