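import math

import numpy as np
import pytest

from sutterbyflow import (
    ChannelGeometry,
    DimensionlessParams,
    DomainError,
    cross_section,
    solve,
    solve_numeric,
)
from sutterbyflow.observables import (
    axial_velocity,
    heat_transfer_coefficient,
    isotherm_grid,
    nusselt,
    pressure_gradient,
    pressure_rise,
    shear_stress,
    stream_grid,
)


@pytest.fixture
def trivial_sol(decoupled_params, flat_section):
    return solve(decoupled_params, flat_section)


@pytest.fixture
def moderate_params():
    return DimensionlessParams(
        Pr=1.0, beta_F=0.1, M=2.0, E_C=0.1, G_R=0.2, G_C=0.2,
        N_T=0.5, N_B=0.5, Sc=0.6, K_R=0.5,
    )


class TestVelocity:
    def test_poiseuille_peak(self, trivial_sol):
        assert axial_velocity(trivial_sol, 0.0) == pytest.approx(1.5)

    def test_no_slip_at_walls(self, baseline_params, baseline_section):
        sol = solve(baseline_params, baseline_section)
        assert axial_velocity(sol, baseline_section.h1) == pytest.approx(0.0, abs=1e-10)
        assert axial_velocity(sol, baseline_section.h2) == pytest.approx(0.0, abs=1e-10)

    def test_even_profile_in_symmetric_channel(self):
        p = DimensionlessParams(G_R=0.0, G_C=0.0)
        geom = ChannelGeometry(a=0.3, b=0.3, m=0.0, omega=0.0)
        section = cross_section(0.4, 0.2, geom)
        sol = solve(p, section)
        eta = np.linspace(0, section.h2, 30)
        assert np.max(np.abs(axial_velocity(sol, eta) - axial_velocity(sol, -eta))) < 1e-10

    def test_outside_channel_rejected(self, trivial_sol):
        with pytest.raises(DomainError):
            axial_velocity(trivial_sol, 1.5)


class TestShearStress:
    def test_newtonian_limit_is_psi_second_derivative(self, flat_section):
        p = DimensionlessParams(beta_F=0.0, M=0.0, G_R=0.0, G_C=0.0)
        sol = solve(p, flat_section)
        eta = np.linspace(-1, 1, 21)
        assert np.allclose(shear_stress(sol, eta), sol.psi.deriv(2)(eta))

    def test_vanishes_at_symmetric_centre(self, trivial_sol):
        assert shear_stress(trivial_sol, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_sutterby_wall_value(self, flat_section):
        """Cubic profile with beta_F=1: psi''(1) = -3, so
        tau = (1 - 9)*(-3) = 24."""
        p = DimensionlessParams(beta_F=1.0, M=0.0, G_R=0.0, G_C=0.0)
        sol = solve(p, flat_section)
        assert shear_stress(sol, 1.0) == pytest.approx(24.0, abs=1e-10)


class TestPressureGradient:
    def test_trivial_limit_value(self, flat_section):
        """psi''' = -3 from the cubic, psi''(0) = 0, body force (Ra/Fr)sin = 1."""
        p = DimensionlessParams(
            M=0.0, G_R=0.0, G_C=0.0, beta_F=0.7, Ra=0.5, Fr=0.5, Lambda=math.pi / 2,
            E_C=0.0, Pr=1.0, N_T=0.0, N_B=0.0, K_R=0.0,
        )
        sol = solve(p, flat_section)
        assert pressure_gradient(p, flat_section, sol) == pytest.approx(-2.0, abs=1e-10)

    def test_everything_off_gives_zero(self):
        p = DimensionlessParams(
            M=0.0, G_R=0.0, G_C=0.0, Lambda=0.0, E_C=0.0, Pr=1.0,
            N_T=0.0, N_B=0.0, K_R=0.0,
        )
        geom = ChannelGeometry(a=0, b=0, m=0, omega=0, Theta=0.0)
        section = cross_section(0.0, 0.0, geom)
        sol = solve(p, section)
        assert pressure_gradient(p, section, sol) == pytest.approx(0.0, abs=1e-12)

    def test_matches_finite_difference_of_same_expression(
        self, moderate_params, baseline_section
    ):
        """Re-derive dp/dxi from dense samples of the assembled solution with
        finite differences instead of polynomial calculus."""
        p = moderate_params
        sol = solve(p, baseline_section)
        e = baseline_section.centre
        h = 1e-3  # balances truncation vs roundoff in the third-derivative stencil
        psi = sol.psi
        d1 = (psi(e + h) - psi(e - h)) / (2 * h)
        d2 = (psi(e + h) - 2 * psi(e) + psi(e - h)) / h**2
        d3 = (psi(e + 2 * h) - 2 * psi(e + h) + 2 * psi(e - h) - psi(e - 2 * h)) / (2 * h**3)
        fd = (
            d3 * (1 - p.beta_F * d2**2)
            - p.lorentz_coefficient * d1
            + p.G_R * sol.theta(e)
            + p.G_C * sol.phi(e)
            + p.Ra / p.Fr * math.sin(p.Lambda)
        )
        assert pressure_gradient(p, baseline_section, sol) == pytest.approx(fd, abs=1e-3)

    def test_consistent_with_oracle_fields(self, moderate_params, baseline_section):
        """The same expression evaluated on the converged collocation fields
        agrees with the cascade value up to truncation (loose bound)."""
        p = moderate_params
        y = solve_numeric(p, baseline_section).interpolant(baseline_section.centre)
        from_oracle = (
            y[3] * (1 - p.beta_F * y[2] ** 2)
            - p.lorentz_coefficient * y[1]
            + p.G_R * y[4]
            + p.G_C * y[6]
            + p.Ra / p.Fr * math.sin(p.Lambda)
        )
        assert pressure_gradient(p, baseline_section) == pytest.approx(
            float(from_oracle), abs=0.1
        )


class TestPressureRise:
    def test_uniform_channel_closed_form(self):
        """Flat channel, couplings off: dp/dxi = -3F/2 + (Ra/Fr)sin(Lambda)
        is constant in xi, so the integral is -2.1 + 1.0 = -1.1."""
        p = DimensionlessParams(
            M=0.0, G_R=0.0, G_C=0.0, Ra=0.5, Fr=0.5, Lambda=math.pi / 2,
            E_C=0.0, Pr=1.0, N_T=0.0, N_B=0.0, K_R=0.0,
        )
        geom = ChannelGeometry(a=0, b=0, m=0, omega=0, Theta=1.4)
        assert pressure_rise(p, geom, t=0.2, quadrature_n=8) == pytest.approx(-1.1, abs=1e-10)

    def test_zero_case(self):
        p = DimensionlessParams(
            M=0.0, G_R=0.0, G_C=0.0, Lambda=0.0, E_C=0.0, Pr=1.0,
            N_T=0.0, N_B=0.0, K_R=0.0,
        )
        geom = ChannelGeometry(a=0, b=0, m=0, omega=0, Theta=0.0)
        assert pressure_rise(p, geom, t=0.0, quadrature_n=8) == pytest.approx(0.0, abs=1e-12)

    def test_quadrature_convergence(self, baseline_params, baseline_geom):
        coarse = pressure_rise(baseline_params, baseline_geom, t=0.2, quadrature_n=64)
        fine = pressure_rise(baseline_params, baseline_geom, t=0.2, quadrature_n=128)
        assert abs(coarse - fine) < 1e-8

    def test_body_force_enters_with_unit_slope(self, baseline_params, baseline_geom):
        """Delta-p is affine in (Ra/Fr)*sin(Lambda) with slope exactly one."""
        variants = [
            baseline_params.replace(Ra=0.5, Fr=0.5, Lambda=math.pi / 2),
            baseline_params.replace(Ra=1.7, Fr=0.8, Lambda=math.pi / 3),
            baseline_params.replace(Ra=0.9, Fr=1.4, Lambda=math.pi / 5),
        ]
        values = [
            (
                p.Ra / p.Fr * math.sin(p.Lambda),
                pressure_rise(p, baseline_geom, t=0.2, quadrature_n=16),
            )
            for p in variants
        ]
        (x0, y0), (x1, y1), (x2, y2) = values
        assert (y1 - y0) / (x1 - x0) == pytest.approx(1.0, abs=1e-9)
        assert (y2 - y0) / (x2 - x0) == pytest.approx(1.0, abs=1e-9)


class TestTrends:
    """Directional responses at the baseline operating point."""

    def test_pressure_rise_increases_with_reynolds(self, baseline_params, baseline_geom):
        values = [
            pressure_rise(baseline_params.replace(Ra=ra), baseline_geom, t=0.2, quadrature_n=16)
            for ra in (0.5, 1.0, 1.5, 2.0)
        ]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_pressure_rise_decreases_with_froude(self, baseline_params, baseline_geom):
        values = [
            pressure_rise(baseline_params.replace(Fr=fr), baseline_geom, t=0.2, quadrature_n=16)
            for fr in (0.5, 1.0, 1.5, 2.0)
        ]
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_nusselt_decreases_with_thermophoresis(self, table_fixed_params, baseline_geom):
        values = [
            nusselt(table_fixed_params.replace(N_T=nt), baseline_geom, 0.4, 0.2)
            for nt in (1.0, 1.5, 2.0, 2.5)
        ]
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_nusselt_decreases_with_brownian_motion(self, table_fixed_params, baseline_geom):
        values = [
            nusselt(table_fixed_params.replace(N_B=nb), baseline_geom, 0.4, 0.2)
            for nb in (0.5, 1.0, 1.5, 2.0)
        ]
        assert all(b < a for a, b in zip(values, values[1:]))


class TestHeatTransfer:
    def test_flat_upper_wall_gives_zero(self):
        p = DimensionlessParams()
        geom = ChannelGeometry(a=0.3, b=0.0, m=0.0, omega=math.pi / 2)
        assert heat_transfer_coefficient(p, geom, 0.4, 0.2) == pytest.approx(0.0, abs=1e-12)

    def test_linear_ramp_closed_form(self):
        """With theta the linear ramp, Z = (m + 2*pi*b*cos(...)) / (h2 - h1)."""
        p = DimensionlessParams(Pr=1.0, N_T=0.0, N_B=0.0, E_C=0.0)
        geom = ChannelGeometry(a=0.3, b=0.3, m=0.2, omega=math.pi / 2)
        xi, t = 0.4, 0.2
        section = cross_section(xi, t, geom)
        slope = geom.m + 2 * math.pi * geom.b * math.cos(2 * math.pi * (xi - t))
        expected = slope / section.width
        assert heat_transfer_coefficient(p, geom, xi, t) == pytest.approx(expected, abs=1e-12)

    def test_consistent_with_oracle_theta(self, moderate_params, baseline_geom):
        xi, t = 0.4, 0.2
        section = cross_section(xi, t, baseline_geom)
        num = solve_numeric(moderate_params, section)
        slope = baseline_geom.m + 2 * math.pi * baseline_geom.b * math.cos(2 * math.pi * (xi - t))
        z_oracle = slope * float(num.interpolant(section.h2)[5])
        z_hpm = heat_transfer_coefficient(moderate_params, baseline_geom, xi, t)
        assert z_hpm == pytest.approx(z_oracle, abs=0.05)


class TestNusselt:
    def test_linear_ramp_slope(self):
        p = DimensionlessParams(Pr=1.0, N_T=0.0, N_B=0.0, E_C=0.0)
        geom = ChannelGeometry(a=0.0, b=0.0, m=0.0, omega=0.0)
        assert nusselt(p, geom, 0.4, 0.2) == pytest.approx(0.5, abs=1e-12)

    def test_walls_coincide_in_symmetric_ramp_limit(self):
        p = DimensionlessParams(Pr=1.0, N_T=0.0, N_B=0.0, E_C=0.0)
        geom = ChannelGeometry(a=0.0, b=0.0, m=0.0, omega=0.0)
        assert nusselt(p, geom, 0.4, 0.2, wall="h1") == pytest.approx(
            nusselt(p, geom, 0.4, 0.2, wall="h2")
        )

    def test_sign_selector(self, baseline_params, baseline_geom):
        plus = nusselt(baseline_params, baseline_geom, 0.4, 0.2, sign=1)
        minus = nusselt(baseline_params, baseline_geom, 0.4, 0.2, sign=-1)
        assert minus == -plus


class TestFieldGrids:
    def test_stream_grid_wall_values(self, baseline_params, baseline_geom):
        pg = stream_grid(baseline_params, baseline_geom, t=0.2, n_xi=9, n_eta=41)
        for i, xi in enumerate(pg.xi):
            section = cross_section(xi, 0.2, baseline_geom)
            inside = ~np.isnan(pg.values[i])
            eta_in = pg.eta[inside]
            sol = solve(baseline_params, section)
            assert np.allclose(pg.values[i, inside], sol.psi(eta_in), atol=1e-12)
            # the outermost retained samples approach the wall data +-F/2
            assert pg.values[i, inside][0] == pytest.approx(
                sol.psi(eta_in[0]), abs=1e-12
            )

    def test_isotherm_grid_masking_and_walls(self, baseline_params, baseline_geom):
        pg = isotherm_grid(baseline_params, baseline_geom, t=0.2, n_xi=7, n_eta=41)
        for i in range(pg.xi.size):
            outside = (pg.eta < pg.h1[i]) | (pg.eta > pg.h2[i])
            assert np.all(np.isnan(pg.values[i, outside]))
            assert np.all(np.isfinite(pg.values[i, ~outside]))

    def test_refinement_consistency(self, baseline_params, baseline_geom):
        """Doubling n_eta keeps the coarse grid's nodes and values (the
        shared global axis makes every coarse node a fine node)."""
        coarse = stream_grid(baseline_params, baseline_geom, t=0.2, n_xi=5, n_eta=51)
        fine = stream_grid(baseline_params, baseline_geom, t=0.2, n_xi=5, n_eta=101)
        assert np.allclose(coarse.eta, fine.eta[::2], atol=1e-14)
        mask = ~np.isnan(coarse.values)
        assert np.allclose(
            coarse.values[mask], fine.values[:, ::2][mask], atol=1e-10, equal_nan=True
        )
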