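# isgel — mechanistic release modelling for in situ forming gel depots

`isgel` models drug release from phase-inverting in situ forming gels
(ISGs): injectable polymer solutions that precipitate into a porous,
drug-releasing matrix on contact with aqueous media. The reference
system is levofloxacin HCl in zein dissolved in DMSO or glycerol formal,
assayed by the cup method (a porcelain cup in 80 mL of pH 6.8 buffer,
emulating a periodontal pocket). The package is for formulation
scientists and modellers who want a tested, reproducible version of the
standard analysis chain: emulate the release experiment, estimate
kinetic parameters by numerical differentiation, sweep predictions, and
forward-simulate the underlying spherical diffusion model.

## The model

The exterior bath concentration `C3(t)` (cumulative release, % of dose)
obeys a linear exchange with the matrix surface:

    dC3/dt + (K32/V3) C3 = (K32/V3) C2(r2),     C3(t0) = 0

with solution

    C3(t) = C2(r2) · (1 − e^{−a (t − t0)}),     a = K32 / V3,

where `C2(r2)` is the drug concentration at the matrix edge (the plateau
of the release curve) and `K32` the matrix-to-bath transfer coefficient
(convention `K32 = a · V3`, `V3` in mL). Estimation inverts the ODE
form `dy/dt + a y = b`: the derivative is discretized with a 2-point
forward stencil (order *h*) or a 5-point central stencil (order *h⁴*),
and `(a, b)` are obtained by ordinary least squares of `dy = b − a·y`;
then `K32 = a·V3` and `C2 = b/a`. On noise-free exponential data the
plateau is recovered with *zero* bias at any step, and all
discretization bias lands on the rate (`a_hat = (1 − e^{−ah})/h` for the
forward stencil — an exact identity the tests pin down).

Beneath the lumped model sits a three-phase spherical depot: a liquid
core (`0 ≤ r < r1`, diffusivity `D1`), a porous matrix shell
(`r1 ≤ r ≤ r2`, diffusivity `D2`, void fraction `ε`) and a well-mixed
bath, with flux matching `D1 ∂C1/∂r = ε D2 ∂C2/∂r` at `r1` and a
Robin-type exchange at `r2`. `isgel.sphere_transport` integrates it
with conservative finite volumes, validated against the classical
series solution for uptake by a sphere.

## Worked example

```python
import numpy as np
from isgel import FirstOrderModel, evaluate_release_curve, fit_release

model = FirstOrderModel.from_K32(K32=56.65, C2_edge=103.50, V3=80.0)
series = evaluate_release_curve(model, np.arange(0, 7.001, 0.001))
fit = fit_release(series, method="forward", V3=80.0)
print(round(fit.model.K32, 2), round(fit.model.C2_edge, 2), round(fit.a_hat, 4))
```

prints

```
56.63 103.5 0.7079
```

i.e. regenerating data from the fitted release equation for the 20%
zein/DMSO formulation and re-estimating returns the transfer coefficient
within 0.04% (the forward stencil's O(h) rate bias at h = 0.001 day) and
the plateau exactly. The `examples/` directory has one short script per
capability (closed-form curves, noisy cup-method fitting, prediction
sweeps, the spherical simulator); each prints the numbers it computes
and a line on what they mean. A thin CLI mirrors the same stages:

```bash
isgel generate --out-dir out --c2 103.5 --k32 56.65
isgel fit --input out/observed.csv --method forward --v3 80 --resample-h 0.001
isgel sweep --out-dir out
isgel simulate-sphere --out-dir out
```

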