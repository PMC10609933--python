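"""Evaluate the closed-form release curve for one depot formulation.

A first-order depot releases drug into the bath following
C3(t) = C2_edge * (1 - exp(-K32/V3 * t)).  Here we use the published
parameters for 20% zein in DMSO (K32 = 56.65, C2 = 103.5% of dose,
V3 = 80 mL) and print the daily cumulative release.
"""

import numpy as np

from isgel import FirstOrderModel, evaluate_release_curve, fraction_released_at

model = FirstOrderModel.from_K32(K32=56.65, C2_edge=103.50, V3=80.0)
series = evaluate_release_curve(model, np.arange(0.0, 8.0))

print("day  cumulative release (% of dose)")
for t, v in zip(series.times, series.values):
    print(f"{t:3.0f}  {v:7.2f}")

print(f"\nfraction of plateau released by day 7: "
      f"{fraction_released_at(model, 7.0):.4f}")
# The curve rises steeply (rate 0.708/day) and has essentially closed on
# its 103.5% plateau within a week: nearly complete release.
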