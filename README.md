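# sutterbyflow

Peristaltic transport of a magnetized **Sutterby nanofluid** in an inclined
tapered channel — a lubrication-limit solver for biofluid pumping problems
(small-vessel hemodynamics, ureteral and gastrointestinal transport) where
the working fluid is shear-dependent, electrically conducting, and carries
nanoparticles.

In the long-wavelength, low-Reynolds limit the flow at one axial station
reduces to a coupled boundary-value problem in the cross-channel coordinate
η for the stream function ψ, temperature θ and concentration φ:

    ψ⁗ (1 − β_F ψ″²) − κ ψ″ + G_R θ′ + G_C φ′ = 0
    θ″/Pr + N_T θ′² + N_B θ′φ′ + E_C M²/D ψ′² + E_C ψ″²(1 − β_F ψ″²) = 0
    φ″ + (N_T/N_B) θ″ − Sc K_R φ = 0

with κ = M²(1+β_eβ_i)/D, D = (1+β_eβ_i)² + β_e² the Hall/ion-slip factor,
no-slip walls carrying ψ = ±F/2 and unit θ/φ ramps.  The package provides:

* **`sutterbyflow.hpm`** — a second-order homotopy-perturbation cascade
  solved by exact polynomial algebra (degree ≤ 9 stream function), with
  per-order polynomials, assembled fields and residual diagnostics;
* **`sutterbyflow.oracle`** — an independent adaptive-collocation solution
  of the same equations for cross-validation;
* **`sutterbyflow.observables`** — velocity, Sutterby shear stress, axial
  pressure gradient and pressure rise per wavelength, heat-transfer
  coefficient Z, Nusselt number, and streamline/isotherm grids;
* **`sutterbyflow.surrogate`** — a 6→5→1 tanh MLP mapping
  (N_T, N_B, M, β_e, β_i, β_F) → Nu, trained by a hand-rolled
  Levenberg–Marquardt optimizer with restart bookkeeping and a
  70/15/15 split;
* **`sutterbyflow.cli`** — a thin `sutterbyflow` command
  (`solve`, `profile`, `pressure`, `sweep`, `grid`, `validate`,
  `ann train|predict|report`, `fixtures`) over YAML/JSON configs.

See `docs/methods.md` for the model, the conventions, and an honest account
of where the second-order cascade is and is not converged.

## Worked example

```python
from sutterbyflow import ChannelGeometry, DimensionlessParams, cross_section, solve
from sutterbyflow.observables import pressure_rise

params = DimensionlessParams()            # baseline: Pr=21, M=2, Hall 0.5, ion slip 0.4
geom = ChannelGeometry()                  # a=b=0.3, taper m=0.2, omega=pi/2, Theta=1.4
section = cross_section(xi=0.4, t=0.2, geom=geom)

sol = solve(params, section)              # order-2 cascade
print(round(float(sol.u(section.centre)), 4))        # 0.985
print(round(float(sol.theta(section.centre)), 4))    # 1.206
print(round(pressure_rise(params, geom, t=0.2), 4))  # -2.5112
```

The centre velocity is just under the parabolic peak (the Lorentz force at
M = 2 flattens the profile), the centre temperature exceeds its wall value 1
because viscous and Joule dissipation at Pr = 21 heat the core, and the
negative Δp at Θ = 1.4 means this flow rate lies beyond the zero-pressure-
rise pumping point (Δp crosses zero near Θ ≈ 0.48; see
`examples/pressure_pumping_curve.py`).

Each script in `examples/` is a short narrative run of one capability:
cross-section profiles, the pumping curve, the reference-series regression,
the two-route validation, and surrogate training.

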