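"""Hypertension on the thin-walled LV surrogate (seconds, no mesh).

Runs a stage-1-like (140 mmHg) and a severe (250 mmHg) pressure step on the
Laplace-equilibrium shell and prints the stability verdict and geometric
drift.  The surrogate shares every constitutive and G&R kernel with the
finite element model but has no transmural structure.
"""

from cardiogr import ScenarioConfig, run_scenario

for p_plus in (140.0, 250.0):
    cfg = ScenarioConfig(model="reduced", steps=[(0.0, p_plus)], horizon=1500.0)
    r = run_scenario(cfg)
    last = r.series.iloc[-1]
    print(
        f"step to {p_plus:.0f} mmHg: verdict={r.verdict} after {r.stop_day:.0f} days; "
        f"thickness {last['thickness']*1e3:.2f} mm, "
        f"diameter {last['diameter']*1e3:.1f} mm, "
        f"collagen fraction {last['collagen_fraction_mean']*100:.1f}%"
    )
# A moderate step converges back to homeostasis (stable); a severe step
# exhibits runaway growth and is cut off by the mass bound (unstable).
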