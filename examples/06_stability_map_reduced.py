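"""Mechanobiological stability map of the thin-wall surrogate (~2 minutes).

Sweeps the growth constant k*T and the pressure step p+ and prints the
verdict grid.  The surrogate is qualitative: the full map belongs to the
finite element model (see docs/methods.md on how the two differ).
"""

import numpy as np

from cardiogr import ScenarioConfig, sweep_stability_map

cfg = ScenarioConfig(model="reduced", horizon=1000.0)
gains = np.array([0.05, 0.1, 0.2])
pressures = np.arange(140.0, 240.0, 20.0)
df = sweep_stability_map(cfg, gains, pressures)
grid = df.pivot(index="gain_times_T", columns="p_plus", values="verdict")
print(grid.to_string())
# "stable" cells return to homeostasis; "unstable" cells exhibit runaway
# growth; cells still converging at the horizon report "undecided".
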