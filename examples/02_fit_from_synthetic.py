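"""Generate a noisy cup-method dataset and re-estimate its parameters.

The cup protocol (80 mL medium, 5 mL aliquots replaced with fresh
buffer, 4 mg dose) is emulated with 2% multiplicative assay noise on the
measured medium concentrations.  The estimation pipeline resamples the
irregular schedule, differentiates, and fits dy = b - a*y.
"""

import numpy as np

from isgel import CupProtocol, NoiseSpec, fit_release, make_dataset, reference_model

model = reference_model("Lv25ZG", "forward")  # K32=34.47, C2=74.01
protocol = CupProtocol()  # 0.5 ... 7 day schedule
noise = NoiseSpec(kind="multiplicative-normal", sd=0.02, seed=11)

truth, observed, meta = make_dataset(model, protocol, noise)
print("observed release (%):", np.round(observed.values, 2))

fit = fit_release(observed, method="forward", V3=80.0, resample_h=0.05)
print(f"\ntrue      K32 = {model.K32:6.2f}   C2 = {model.C2_edge:6.2f}")
print(f"estimated K32 = {fit.model.K32:6.2f}   C2 = {fit.model.C2_edge:6.2f}")
print(f"rel_err = {fit.rel_err:.4f}   r^2 = {fit.r_squared:.4f}")
# With 2% assay noise on 8 samples the transfer coefficient and plateau
# come back within a few percent; rel_err is the 2-norm misfit of the
# reconstructed curve and r^2 its coefficient of determination.
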