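# Methods

## Physical model

We treat a monovalent salt (NaCl by default) confined in a cylindrical pore
of radius R and length L at bulk reservoir molarity c_s. The aspect ratio is
assumed high (L ≫ R; the `PoreModel` constructor warns below L/R = 100), so
concentrations depend only on the radial coordinate and entrance/access
resistance is neglected. Ion mobilities and the solvent viscosity take their
dilute-limit bulk values — an assumption known to be good for pore diameters
above roughly 3 nm and to overestimate transport by at most ~25% below that.
The reduced electrostatic potential φ(r) (units of k_BT/e) obeys the radial
Poisson–Boltzmann equation with the wall Gauss condition
φ′(R) = 4π ℓ_B σ/e; local partition coefficients are k±(r) = e^∓φ and
pore averages are area averages. σ is stored signed (negative by
convention, cations as counter-ions); a sign flip swaps the ion roles
symmetrically, and all conductivities depend on σ only through |σ| and σ².

Three nested descriptions are implemented and cross-checked against each
other:

1. **Homogeneous (Donnan)**: φ uniform, fixed by electroneutrality;
   k̄± = √(1+X²) ± X with X = |σ|/(e R n_s). Valid for dimensionless
   surface charge σ* = 2π ℓ_B R|σ|/e ≲ 1.
2. **Good co-ion exclusion (GCE)**: counter-ions only; the PB equation then
   has the closed-form solution φ = 2 ln(1 − α²r²), α² = t/R²,
   t = σ*/(2+σ*), from which the electro-osmotic conductivity integral
   evaluates to σ²F(σ*)/(2η) with F = 4/σ* − (8/σ*²)ln(1+σ*/2).
3. **Full numerics**: damped-Newton solution of the nonlinear PB equation
   on a uniform radial grid, plus the PNP conductivity integrals — the
   independent oracle for the closed forms.

The production forward model is the hybrid sum κ = κ_em(Donnan) +
κ_ad(GCE) + κ_slip, exact in both limits above. The slip term
2σ²b/(ηR) is exact within PNP because the plug-flow velocity couples only
to the net in-pore charge, which electroneutrality pins to the wall charge.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| D₊, D₋ | 1.334e-9, 2.032e-9 | m²/s | dilute-limit NaCl at 25 °C |
| T | 298.15 | K | reference temperature |
| η | 8.94e-4 | Pa·s | bulk water viscosity at 25 °C |
| ε_w | 78.3 | – | bulk water |
| L | 6e-6 | m | experimental pore length of the track-etched channels |
| b | 0 or 30e-9 | m | no-slip vs a typical uncharged-hydrophobic-wall value |
| χ(c_s) | off | – | high-concentration ion–ion correction; user-supplied table, neglected by default |
| ε_m | 3.0 | – | typical polymer/oxide membrane permittivity |

Derived scales at these defaults: ℓ_B = 0.716 nm, λ_DH(0.1 M) = 0.96 nm.

## Fitting protocol

Two models are fit to (c_s, G) tables: phenomenological
G = (πR²/L)κ_b(c_s)[χ] + G_r over (R, G_r), and mesoscopic
G = (πR²/L)κ_hybrid(c_s; R, σ, b) over (R, |σ|) with b held fixed — b and σ
are degenerate on the plateau (both enter the c_s-independent part), so the
API forbids fitting them jointly. Residuals are taken in log G because the
data span ~4 decades in c_s and ~3 in G; linear residuals would let the
bulk branch dominate. Optimization is bounded trust-region least squares in
log-parameters (bounds R ∈ [0.2, 50] nm, |σ| ∈ [1e-4, 1] C/m²,
G_r ∈ [1e-14, 1e-9] S) from a physics-based start (R from the bulk branch,
G_r from the plateau) plus seeded log-uniform restarts (10 by default).
Standard errors are Gauss–Newton covariances at the optimum, propagated
from log scale; they are approximate (no full profile likelihood).

## Numerical choices

* **PB solver**: uniform grid, 2000 intervals by default; second-order
  stencils with the axis regularized as ∇²φ(0) → 4(φ₁−φ₀)/h² and a ghost
  node enforcing the wall Neumann condition; damped Newton (steps capped at
  2 k_BT/e) on the tridiagonal Jacobian until the max update < 1e-10. The
  Donnan potential is the initial guess. Discretization, not the Newton
  tolerance, limits accuracy: the trapezoidal k̄± carry O(h²) ≈ 1e-6–1e-5
  relative error at the default grid, which is the advertised accuracy of
  the electroneutrality identity and of grid-refinement convergence.
  c_s = 0 is rejected (the grand-canonical reference is the bulk); the GCE
  closed form covers that limit.
* **F(σ*)**: closed form for σ* ≥ 1e-3, 5-term Taylor series below
  (continuous to ~1e-12 at the switch, cancellation-free via `log1p`).
* **Donnan coefficients**: the co-ion coefficient is computed as
  1/k_counter — the exact algebraic reciprocal — to avoid the
  √(1+X²) − X cancellation at large X (very low salt).
* **Dielectric self-energy**: the pore correction to the Debye–Hückel
  Green function is a sum over angular modes m with an axial-wavenumber
  Gauss–Legendre quadrature (k = s·u/(1−u), s = κ_v + 1/R, 160 nodes);
  matching coefficients are evaluated through Bessel logarithmic
  derivatives and a log-domain K·I²/I combination, stable at large m and
  extreme arguments. The mode sum (30 modes by default) is accelerated by
  a geometric tail estimate. The image self-energy diverges
  logarithmically at the wall, so pointwise ΔW within ~2% of the wall is
  cutoff-limited by design; the Γ integral (Gauss–Legendre in r, 32 nodes)
  is converged to ~1e-3 at the defaults, verified by doubling all cutoffs.
  A guard raises when the estimated tail dominates at radii where the
  Boltzmann factor is non-negligible (ΔW < 6 k_BT).
* **Γ fixed point**: κ_v² = Γκ_b², iterated from Γ₀ = 1 with full steps
  (the map is monotone; a damping knob exists), stopping at |ΔΓ| < 1e-10.
* **Profiles**: half-open bins [iΔr, (i+1)Δr), assignment by floor(r/Δr),
  Δr = 0.05 nm by default; particles at/beyond the last edge are counted in
  an overflow tally, never binned. Count conservation (Σ conc·volume =
  mean count) is exact by construction. The water-accessible diameter is
  defined as twice the outer edge of the outermost bin whose concentration
  ratio exceeds a threshold (0.05 by default) — an edge-based estimator; an
  offset-based alternative (nominal diameter minus twice a wall-exclusion
  distance) is provided separately since the shell-edge criterion is not
  unique.

## Synthetic data

The generators emulate the experimental pipeline at its actual operating
conditions: voltage-clamp protocols of 0–200 mV in 10 mV steps; conductance
datasets on 13 log-spaced molarities covering 1e-4–5 mol/l with 5%
multiplicative log-normal noise (conductances span decades, so errors are
relative); optional two-state Markov telegraph switching of the conductance
with user dwell times, mimicking metastable wetting/dewetting oscillations
of sub-5-nm hydrophobic pores (dwell statistics are free parameters — only
the phenomenon, not its kinetics, is modeled); and Poisson-placed particle
snapshots with Gaussian radial shells and a hard exclusion radius,
reproducing the layered water structure near a hydrophobic wall. All
generators are pure functions of (parameters, seed).

What passing tests on these fixtures do **not** show: real measurements
add 1/f and instrument noise, access resistance, electrode drift, and
concentration-dependent mobilities; real MD water has correlated (not
Poisson) density fluctuations. The recovery statistics quoted by the
acceptance script are therefore statements about the estimator under the
stated noise model, not about experimental accuracy.

## Known limitations

* Axial invariance: no entrance effects or access resistance; conductances
  of short pores (L/R < 100) are outside the model's domain.
* The approach of G(c_s) to the bulk line at high salt is from above only
  while surface conduction dominates; for NaCl (μ₋ > μ₊) in a negative pore
  the migration term crosses slightly below bulk at very high c_s — a real
  property of the model family, reflected in the tests.
* The dielectric module is interpretive (κ_em-level corrections with a
  charge-independent Γ); it is not coupled into the fitting pipeline, and
  the charged-pore dielectric/PB coupling beyond this semi-homogeneous
  approach is out of scope.
* Multivalent ions, temperature-dependent solvent properties, and
  concentration-dependent in-pore mobilities beyond the optional χ table
  interpolation are not modeled.

## Problem sizes

Default study sizes, chosen so the whole suite replays in well under a
minute of CPU: PB grids of 2000 intervals; 13-point conductance datasets;
50 Monte-Carlo replicates for recovery statistics; 100 random draws for the
electroneutrality invariant; 200 seeds for the I–V estimator calibration;
6-snapshot particle fixtures of ~3e4 particles.
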