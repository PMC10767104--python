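# Methods

## Model

`sutterbyflow` models peristaltic pumping of an electrically conducting
Sutterby nanofluid through a two-dimensional inclined tapered channel under
a transverse magnetic field with Hall and ion-slip currents.  In the
long-wavelength, low-Reynolds (lubrication) limit, and in the frame moving
with the wall wave, the problem at one axial station reduces to a coupled
boundary-value problem in the cross-channel coordinate η for the stream
function ψ, temperature θ and nanoparticle concentration φ:

    ψ⁗ (1 − β_F ψ″²) − κ ψ″ + G_R θ′ + G_C φ′ = 0
    θ″/Pr + N_T θ′² + N_B θ′ φ′ + E_C M²/D ψ′² + E_C ψ″² (1 − β_F ψ″²) = 0
    φ″ + (N_T/N_B) θ″ − Sc K_R φ = 0

with κ = M²(1 + β_e β_i)/D and D = (1 + β_e β_i)² + β_e².  The walls are

    h₂(ξ,t) =  1 + m ξ + b sin 2π(ξ−t),
    h₁(ξ,t) = −1 − m ξ − a sin 2π(ξ−t+ω/2π),

and carry no-slip, prescribed stream-function values ±F/2 (F the local flow
rate, F = Θ + a sin(2π(ξ−t)+ω) + b sin 2π(ξ−t)) and unit temperature /
concentration ramps.  The axial pressure gradient is recovered afterwards as

    dp/dξ = ψ‴(1 − β_F ψ″²) − κ ψ′ + G_R θ + G_C φ + (Ra/Fr) sin Λ.

The momentum equation above is the once-differentiated pressure-gradient
relation *without* the chain-rule term −2β_F ψ″ψ‴·(…) that strict
differentiation would add.  We keep this form deliberately — the solver, the
residual diagnostics, and the numerical cross-check all use the identical
system, so the two solution routes differ by truncation only.  The relation
"Q = F + d + 1" connecting the flow-rate constants mixes a dimensional
half-width symbol into a dimensionless statement; with the half-width scaled
to one it reads Q = F + 2.  It is recorded for completeness and consumed
nowhere.

## Homotopy-perturbation cascade

The solver embeds the system in a family indexed by p ∈ [0,1] whose linear
part is the bare highest derivative, expands each unknown to second order in
p, and collects powers: order zero is ψ₀⁗ = 0, θ₀″ = 0, φ₀″ = 0 (a Hermite
cubic and two linear ramps); each higher order is a linear problem whose
polynomial forcing is assembled from lower orders by exact coefficient
algebra (`numpy.polynomial.Polynomial`; no collocation or truncation inside
the cascade).  Each linear problem is solved by antidifferentiating the
forcing and fixing the 2 or 4 integration constants from the boundary data —
a dense solve of a tiny Vandermonde-type system.  At second order
deg ψ ≤ 9 and deg θ ≤ 8 for generic parameters.

**Boundary-condition allocation.**  Order zero carries the full boundary
data; all higher orders are homogeneous.  This is the only allocation under
which the assembled sum satisfies the boundary conditions identically at
every truncation order, and the package enforces it as the default (a
`split` mode that shares the data equally across orders is retained for
sensitivity studies).  A property test asserts all eight assembled boundary
values to 1e−10 over 100 random parameter draws.

**Convergence caveat.**  The homotopy moves the energy equation's second
derivative from θ″ (linear part) to θ″/Pr (full operator), so the linear
portion of the temperature cascade contracts only by (1 − 1/Pr) per order.
At the blood-like baseline Pr = 21 this is ≈ 0.95: a second-order truncation
is far from converged for θ, and the attached residual diagnostics (max-norm
residuals of the three equations on a uniform 201-point grid) make this
visible — the energy residual at the baseline is O(1).  The velocity field
is much less affected because the momentum equation's linear part is not
Pr-scaled.  Consequences are quantified below under "Two-route comparison".

## Reference-series regression

At the fixed reference set (Pr=21, N_B=0.5, G_C=0.2, β_F=1, G_R=0.2,
β_i=0.4, β_e=0.5, N_T=1, K_R=0.5, Sc=0.6, ξ=0.4, t=0.2, E_C=0.1, Θ=1.4,
M=1, a=b=0.3, ω=π/3, m=0.2) the package reproduces the tabulated
ten-significant-figure series coefficients.  Two findings from the fixture
runner (`sutterbyflow.fixtures.run_fixture_suite`) matter for
reproducibility:

1. **Taper.**  The reference series corresponds to m = 0.2 (with m = 0 the
   tabulated polynomials violate their own boundary data by ~0.15).
2. **Input precision.**  The tabulated polynomials satisfy the boundary
   data *exactly* at walls h₁′ = −1.3031777, h₂′ = 1.3652578 — the values
   obtained when the wall sinusoids and ω = π/3 are evaluated with π
   truncated to 3.14.  Under that input variant our cascade matches every
   tabulated ψ and θ coefficient to ≤ 2e−8 relative, which pins down the
   cascade algebra term by term.  With exact-π inputs the walls shift in the
   fourth decimal and the coefficients move by ~3e−5 to 5e−3 relative.  The
   package always uses exact π; the fixture runner records the variant.

The tabulated concentration series is a verbatim copy of the stream-function
series (dimensionally impossible, since φ must reach 1 at the upper wall),
so no φ regression exists.

## Numerical cross-check (oracle)

`sutterbyflow.oracle.solve_numeric` solves the same three equations with no
perturbation expansion: an 8-component first-order system under
`scipy.integrate.solve_bvp` (adaptive collocation, default tolerance 1e−8),
initialised from the order-zero closed form.  The explicit form divides by
the Sutterby factor 1 − β_F ψ″²; if that factor crosses zero on the initial
or converged mesh the solver raises `DegenerateSutterbyFactor`, because the
quasilinear operator is then singular.  This is not hypothetical: at the
baseline flow rate, ψ″ reaches ≈ ±2.3 at the walls, so any β_F ≳ 0.2 makes
the factor change sign.  The reference set's β_F = 1 is therefore outside
the oracle's range (the cascade itself never divides and is unaffected).

**Two-route comparison.**  In the decoupled closed-form limit both routes
agree to better than 1e−7.  At the baseline operating point the velocity
agrees to max-norm ≈ 0.017, but the temperature differs by O(1)
(cascade max θ ≈ 1.25 vs converged ≈ 1.85): the visual coincidence of the
two methods claimed for the temperature field cannot be quantitatively true
at Pr = 21 with a second-order cascade.  The acceptance suite asserts the
0.05 band for both u and θ as stated; the θ case fails and is left failing,
with this section as the analysis.

## Baseline operating point and defaults

Pr = 21, N_B = 0.5, N_T = 1, E_C = 0.1, G_R = 0.2, β_i = 0.4, β_e = 0.5,
Sc = 0.6, M = 2, m = 0.2, a = b = 0.3, t = 0.2, Θ = 1.4, ω = π/2, Fr = 0.5,
Ra = 0.5.  Values the baseline list leaves open are fixed once as package
defaults:

* **β_F = 0.1.**  The effective viscosity μ_eff ∝ 1 − β_F ψ″² must stay
  positive for the model to be physically meaningful and for the explicit
  oracle ODE to be regular; at the baseline flow rate this requires
  β_F ≲ 0.2, and 0.1 leaves a comfortable margin (factor ≥ 0.47 across the
  channel).  The reference-series set overrides this with its own β_F = 1.
* **G_C = 0.2, K_R = 0.5** from the reference-series list.
* **Λ = π/2** (the first value of the inclination sweep; sin Λ = 1 makes
  the body-force term maximal and easy to reason about).
* **ξ = 0.4** for single-station work, matching the reference station.

## Observables and conventions

* dp/dξ retains an η dependence in the lubrication limit; the evaluation
  point defaults to mid-channel (symmetric choice) and is selectable
  (either wall, or the cross-sectional Gauss–Legendre average).
* Pressure rise per wavelength Δp = ∫₀¹ (dp/dξ) dξ by 64-node
  Gauss–Legendre, re-solving the cascade at every node's cross-section; 64
  vs 128 nodes agree to < 1e−8 at the baseline (the integrand is smooth for
  an open channel).
* Heat-transfer coefficient Z = (∂h₂/∂ξ)·θ′(h₂) with
  ∂h₂/∂ξ = m + 2πb cos 2π(ξ−t); Nusselt number Nu = θ′(h₂).  Both are
  package conventions — the symbols are used without definition in the
  source formulation — and both expose wall/sign selectors.  The fixture
  runner sweeps sign × wall × {m} × {ω} against the first tabulated Nu row
  (0.315924) and finds no convention closer than ≈ 0.23; the tabulated Nu
  values are therefore treated as unreproducible point values, while their
  *directional* structure (Nu decreasing along the N_T and N_B columns) does
  hold under the default convention and is asserted.
* Streamline/isotherm grids sample per-station cascade solutions on a
  shared (ξ, η) mesh, NaN-masked outside [h₁(ξ), h₂(ξ)].  Closed-contour
  ("trapping bolus") detection is left to the plotting layer.

## Directional claims that the equations refute

Two directional statements in the accompanying prose are inconsistent with
the equations as given, and the corresponding acceptance assertions are left
failing rather than silently inverted:

* **Δp vs inclination Λ.**  The body force enters additively as
  (Ra/Fr) sin Λ, so Δp is *increasing* in Λ on (0, π/2] (slope
  (Ra/Fr) cos Λ ≥ 0); measured: Δp = −2.92, −2.80, −2.65, −2.51 at
  Λ = π/5, π/4, π/3, π/2.  The claimed decrease most likely comes from
  reading the sweep legend (π/2, π/3, π/4, π/5) as an increasing sequence.
* **Centre velocity vs Hall parameter β_e.**  At fixed flow rate, raising
  β_e weakens the Lorentz damping κ, the profile relaxes from plug-like
  toward parabolic, and the centre velocity *rises* (0.971 → 1.033 over
  β_e = 0.1 → 3 at the baseline).  A decrease would require comparing at
  fixed pressure gradient instead, which the boundary conditions here do
  not do.

Δp increasing in Ra, Δp decreasing in Fr, and Δp affine in (Ra/Fr) sin Λ
with unit slope all hold exactly as the equations imply.

## MLP surrogate

A 6→5→1 perceptron (tanh hidden layer, linear output, 41 weights) maps
(N_T, N_B, M, β_e, β_i, β_F) to Nu.  Features and target are min–max scaled
to [−1, 1]; rows are split 70/15/15 uniformly at random with a stored seed.
Training is Levenberg–Marquardt on the training split with the analytic
Jacobian: solve (JᵀJ + λI)δ = −Jᵀr, multiply λ by 10 on rejection and divide
by 10 on acceptance (λ₀ = 1e−3, max 200 iterations, 20 restarts from
seed-derived initial weights by default).  Accepted steps strictly decrease
the training SSE — asserted on every run — and the whole procedure is
bitwise deterministic for a given seed.  None of λ₀, the factor 10, the
iteration cap or the restart count is prescribed by the formulation; they
are common LM-MLP practice and config-exposed.

On the 18 embedded benchmark rows the training split (≈ 13 rows) is
interpolated to machine precision by the 41-weight network, so the best MSE
over restarts and splits lands far below the tabulated 2.09144e−7 (whether
that figure is a train, test or pooled error is unstated; we report all
three splits and compare the minimum).  Validation/test MSEs on held-out
rows are O(1e−4): with ≤ 3 rows per held-out split they are noisy estimates
of generalization, not headline numbers.

## What the synthetic data does and does not emulate

The surrogate's training data are exact solver outputs on noiseless
parameter grids — there is no measurement error, no parameter jitter, and
Nu varies smoothly over the box.  Passing fits therefore demonstrate the
trainer and architecture, not robustness to experimental noise.  Likewise
all transport fields are smooth polynomials by construction; nothing here
probes boundary layers sharper than a degree-9 polynomial can represent,
which is precisely the regime (large Pr·E_C) where the cascade is known to
be unconverged.

## Numerical choices

Double precision throughout.  Cascade: exact polynomial algebra; boundary
systems solved densely (4×4 worst case).  Residual diagnostics on a uniform
201-point grid (config-exposed).  Oracle: `solve_bvp` tol 1e−8,
initial mesh 101 nodes, cap 100 000; Sutterby-factor floor 1e−8.
Coefficient regressions at rtol 1e−6 (the tabulated values carry 10
significant figures; input rounding dominates beyond that).  Quadratures:
Gauss–Legendre (64 nodes for Δp, 32 for cross-sectional averages).  Angles
are radians everywhere; the config layer accepts "pi/3"-style strings.
N_T = 0 is treated as fully decoupling the species equation from θ even if
N_B = 0 (the N_T/N_B ratio is defined as 0 in that case); N_B = 0 with
N_T > 0 is flagged by `validate_params` and rejected by the config schema.

## Known limitations

* Truncation is fixed at order ≤ 2; no Padé or other acceleration.  At
  large Pr the temperature field should be taken from the oracle, not the
  cascade.
* The full wave-number-retaining two-dimensional equations are out of
  scope; everything is the lubrication reduction.
* The oracle cannot cross a vanishing Sutterby factor; parameter sets with
  β_F ψ″² ≥ 1 anywhere are solvable by the cascade only, with no independent
  check.
* Tabulated Nu point values are unreproducible (undefined convention);
  only their directional structure is validated.
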