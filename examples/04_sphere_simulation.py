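"""Forward-simulate the three-phase spherical depot.

A 3 mm depot with a 1 mm porous matrix shell (void fraction 0.3)
releases drug into an 80 mL bath.  The simulator solves spherically
symmetric diffusion in the core and shell coupled to a well-mixed
exterior, and reports the bath content as cumulative percent released.
"""

import numpy as np

from isgel import SphereSpec, simulate
from isgel.sphere_transport import total_drug_mass

spec = SphereSpec(
    r1=2.0, r2=3.0,            # core / outer radii, mm
    D1=0.5, D2=0.05,           # diffusivities, mm^2/day
    epsilon=0.3,               # matrix void fraction
    K32=50.0, V3=80.0,         # bath exchange (K32 = rate * V3 convention)
    C1_init=1.0,               # uniform initial core concentration
    t_grid=tuple(np.linspace(0.0, 7.0, 8)),
    n_r=40,
)

states, series = simulate(spec)
m0 = total_drug_mass(spec, states[0])
drift = max(abs(total_drug_mass(spec, s) - m0) for s in states) / m0

print("day  released (% of dose)   core centre C1")
for s, v in zip(states, series.values):
    print(f"{s.time:3.0f}  {v:10.3f}            {s.C1_field[0]:.4f}")
print(f"\nmass-budget drift over the run: {drift:.2e} (relative)")
# Release is much slower than the fitted first-order curves with the
# same K32: here matrix diffusion (D2) is rate limiting, illustrating
# how the lumped transfer coefficient folds several resistances into one.
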