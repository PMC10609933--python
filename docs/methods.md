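# Methods

## Scope and units

`isgel` implements the analysis chain for cumulative drug-release data
from phase-inverting gel depots: closed-form first-order release
(`release_core`), cup-method data emulation (`synthetic_data`),
finite-difference estimation of the release parameters
(`finite_differences`, `first_order_fit`), and a forward simulator of
the three-phase spherical transport model (`sphere_transport`). Units
are fixed package-wide: time in days, volume in mL, radii in mm,
release in % of nominal dose.

## The first-order release model

The bath concentration obeys `dC3/dt + a C3 = a C2_edge` with
`a = K32/V3`, giving `C3(t) = C2_edge (1 − e^{−a(t−t0)})`. `C2_edge` is
the drug concentration at the outer matrix edge — the plateau the
release curve approaches — and `K32` the matrix-to-bath transfer
coefficient. `K32` is carried in the tabulated convention
`K32 = a · V3` with `V3` in mL (so it is numerically mL/day although
reported per day); the identity `rate = K32/80` holds across all eight
tabulated reference rows in `formulations.py`, which is how the
convention is fixed. `t0` defaults to 0 (injection time) and is
configurable for lag modelling.

## Parameter estimation

The ODE is linear in `(a, b)` once `dy/dt` is replaced by a
finite-difference estimate, so the estimator is ordinary least squares
of `dy = b − a y` over the stencil nodes, followed by `K32 = a V3`,
`C2_edge = b/a`. Design choices:

- **Stencils.** 2-point forward (order h, anchored at the left node,
  nodes 0..n−2) and 5-point central (order h⁴, anchored at the centre,
  nodes 2..n−3). Nodes without a full stencil are dropped — no
  one-sided fallback — so every estimate is at its advertised order.
- **Exactness anchor.** On noise-free data `y = C(1 − e^{−at})` both
  stencils satisfy `dy_i = a_h (C − y_i)` *exactly*, with
  `a_h = (1 − e^{−ah})/h` (forward) or
  `a_h = (16 sinh(ah) − 2 sinh(2ah))/(12h) = a − a⁵h⁴/30` (central).
  Hence the regression is exact, `C2_edge` is recovered with zero bias
  at any step, and the rate bias is O(h) / O(h⁴). The tests assert
  these identities to 1e−8 relative and the empirical log–log
  convergence slopes (1 and 4, ±0.2).
- **Non-uniform schedules** are resampled with monotone
  shape-preserving PCHIP interpolation before differencing; a grid is
  accepted as uniform when successive gaps agree to 1e−6 relative.
- **Fit origin.** `t0` for diagnostics is the first sample time when
  the series starts at zero release, otherwise 0; the regression itself
  never uses `t0`.
- **Diagnostics** are computed against the reconstructed closed-form
  curve on the original sample times: `rel_err = ‖y − ŷ‖₂/‖y‖₂` and
  `r² = 1 − SSres/SStot`. Nonlinear least squares on the exponential
  directly is deliberately not a product feature (it serves only as a
  cross-check in tests); the finite-difference route is the method
  under study.
- **Failure modes.** Constant series raise a degenerate-design error;
  an estimated `a ≤ 0` raises a non-physical-fit error that carries the
  raw estimates.

## Cup-method emulation

The generator reproduces the reference protocol: 80 mL medium, 5 mL
aliquots replaced with fresh buffer, 4 mg dose (0.4 g of formulation at
1% w/w drug), sampled 0.5–7 days. Aliquot withdrawal depletes the
medium, so per-sample concentrations follow
`c_n = (A_n − Vs Σ_{i<n} c_i)/V3` and the standard cumulative-percent
correction `A_n = c_n V3 + Vs Σ_{i<n} c_i` inverts it exactly (property
tested to 1e−12 over random monotone truths). Noise is applied to the
medium concentrations — the quantity a spectrophotometer actually
measures — so it propagates through the correction the way real assay
error does; options are additive or multiplicative Gaussian, seeded,
and never clipped (negative values near the detection limit stay
visible). The dose is a free parameter because the percent
normalization cancels it in every fitting target; 4 mg is the default
implied by the protocol masses. What the generator does **not**
emulate: assay interference from co-released solvent, inter-replicate
variability of matrix formation, or any deviation from first-order
truth — so passing recovery tests demonstrate correctness of the
estimation chain, not validity of the first-order law for real depots.

## Spherical three-phase simulator

Geometry: liquid core (`0 ≤ r < r1`), porous matrix shell
(`r1 ≤ r ≤ r2`, void fraction ε, concentrations per void volume),
well-mixed bath (`V3`). Both radial phases obey
`∂C/∂t = (D/r²) ∂/∂r (r² ∂C/∂r)`; the centre condition is zero radial
gradient (the symmetry condition); at `r1` concentration is continuous
with flux matching `D1 ∂C1/∂r = ε D2 ∂C2/∂r`; at `r2` a Robin-type
balance equates the matrix flux with the bath exchange
`V3 dC3/dt = K32 (C2(r2) − C3)`, with the surface value obtained from
the series conductance of the matrix half-cell and `K32`. The shell is
initialised linearly between core and bath concentrations. Interface
radii are static (quasi-static geometry): the moving-boundary phase
inversion dynamics have no closed governing equations here and are out
of scope, as are solvent/water transport and polymer precipitation
kinetics. Only the drug species is simulated.

Numerics: conservative second-order finite volumes on uniform per-phase
grids (default 40 cells per phase), method of lines, stiff BDF
integration with rtol 1e−6 / atol 1e−9 and a tridiagonal Jacobian
sparsity pattern. Because the semi-discrete system is written in
surface fluxes, total drug (core + void space + bath) is a linear
invariant and is conserved to solver round-off (observed ~1e−15,
asserted < 1e−6). Validation: a single-phase constant-surface
configuration (D1 = D2, ε = 1, r1 = r2/50, uniform zero initial field,
bath clamped) reproduces the classical series
`1 − (6/π²) Σ m⁻² e^{−m²π²τ}` for fractional uptake to ≤ 1e−3 absolute
at τ ∈ {0.02, 0.05, 0.1, 0.3} with 200 cells. The series function
returns its limit 0 exactly at τ = 0, where truncation converges only
as 1/n. No numeric values of `D1, D2, ε, r1, r2` are published for the
reference system, so the simulator ships with a plausible synthetic
depot (3 mm sphere, 1 mm shell, ε = 0.3) and is validated against
analytic limits rather than data.

## Reference parameter sets

`formulations.py` tabulates the eight published (formulation × scheme)
estimates of `(K32, C2_edge)` for levofloxacin–zein depots in DMSO/
glycerol formal. They are treated as inputs: the recovery tests and the
acceptance script regenerate noise-free data from each row's release
equation (grid 0–7 days; h = 0.001 for the forward scheme, 0.01 for the
central scheme — steps at which the rate bias is ≤ 0.04%) and require
the re-fit to return `K32` within 0.5% and `C2_edge` within 0.1%
relative. The published relative errors (≈1.3–1.6) and r² (≈0.977–
0.996) refer to experimental curves that were never made publicly available
and therefore cannot be recomputed; the metric definitions themselves are
unit-tested on worked examples instead.

## Statistical robustness check

With 2% multiplicative assay noise the seed-averaged rate estimate over
200 replicates must fall within 3 standard errors of the generator
rate. This check uses the central scheme on a uniform 0.1-day schedule:
the central stencil excludes the anchor node, so the regressor's own
measurement error does not leak into the response and the estimator
stays unbiased to first order; the forward stencil at fine steps would
instead show a genuine errors-in-variables bias (response noise
correlated with regressor noise, growing as 1/h), which is a property
of that estimator, not a bug.

## Known limitations

- The lumped model compresses all transport resistances into one
  first-order rate; the simulator shows regimes (small `D2`) where the
  release is matrix-diffusion limited and visibly non-exponential.
- Static interface radii ignore swelling and erosion.
- The estimator assumes uniform sampling after optional resampling;
  heavy-tailed or correlated assay noise is not modelled.
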