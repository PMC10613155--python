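"""Maxwell-analog stress relaxation of a single material point.

Stretches a mixture point a fraction beyond homeostasis, freezes the total
stretch, and lets turnover remodel the constituents.  The fiber stress decays
exponentially back to the set point with the mean survival time as the time
constant — the behavior of a Maxwell element in parallel with a motor unit
exerting the homeostatic stress.
"""

import numpy as np

from cardiogr import PointDriveProtocol, drive_material_point, human_lv_mixture

mix = human_lv_mixture()
T = mix.myocyte.T_survival

proto = PointDriveProtocol(
    control="stretch", schedule=[(0.0, 1.004)], duration=5 * T, dt=0.1
)
df = drive_material_point(proto, mix)

sig = df["sigma_myocyte"].to_numpy()
t = df["time"].to_numpy()
dev0 = sig[0] - 22e3
fit_tau = -t[-1] / np.log((sig[-1] - 22e3) / dev0)
print(f"initial overstress: {dev0/1e3:+.3f} kPa")
print(f"fitted decay time constant: {fit_tau:.2f} days (survival time T = {T} days)")
print(f"residual deviation after 5 T: {(sig[-1]-22e3)/dev0*100:.2f}% of initial")
# The fitted time constant matches T to within the linearization error.
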