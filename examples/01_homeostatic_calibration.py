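"""Homeostatic set points of the myocardial mixture.

Builds the baseline human-LV parameter set and evaluates the fiber Cauchy
stress of each constituent at its homeostatic elastic stretch — the set
points that mass turnover and remodeling drive the tissue back toward.
"""

import numpy as np

from cardiogr import DeformationState, constituent_fiber_cauchy_stress, human_lv_mixture
from cardiogr.lv_model import homeostatic_stresses

mix = human_lv_mixture()
print(f"calibrated initial active stretch: {mix.lambda_act0:.6f}")

state = DeformationState(
    F=np.eye(3),
    f0=np.array([1.0, 0.0, 0.0]),
    lambda_r=np.array([1.0 / mix.myocyte.lambda_h]),
    G3D=np.eye(3),
)
sigma_m = constituent_fiber_cauchy_stress(state, mix.myocyte, mix)
print(f"myocyte stress at lambda_e = {mix.myocyte.lambda_h}: {sigma_m/1e3:.2f} kPa")

for name, sh in zip([p.name for p in mix.fibers], homeostatic_stresses(mix)):
    print(f"  sigma_h[{name}] = {sh/1e3:8.2f} kPa")

# The myocyte value (22 kPa) anchors the stress convention; the collagen set
# point (~206.5 kPa at lambda_h = 1.062) follows from the same convention.
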