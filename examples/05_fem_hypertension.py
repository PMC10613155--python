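"""Stage-1 vs stage-2 hypertension on the finite element LV (~2 minutes).

Prestresses a coarse ventricle at 120 mmHg, settles G&R, then applies
Heaviside pressure steps to 140 mmHg (stage 1) and 180 mmHg (stage 2) and
integrates the coupled growth/remodeling/equilibrium problem until the
stability classifier fires.
"""

import copy

from cardiogr import ScenarioConfig, prepare_baseline, run_scenario

cfg = ScenarioConfig(
    model="fem", target_elements=1500, order=1, dt=2.5, eps_pre_mm=0.01,
    settle_steps=100, horizon=2000.0,
)
base = prepare_baseline(cfg)
print(
    f"baseline ready: prestress {base.prestress_report.iterations} iterations, "
    f"residual {base.prestress_report.final_displacement*1e3:.4f} mm"
)

for p_plus in (140.0, 180.0):
    c = copy.deepcopy(cfg)
    c.steps = [(0.0, p_plus)]
    r = run_scenario(c, baseline=base)
    last = r.series.iloc[-1]
    print(
        f"step to {p_plus:.0f} mmHg: {r.verdict} after {r.stop_day:.0f} days; "
        f"wall thickness {last['thickness']*1e3:.2f} mm, "
        f"endocardial diameter {last['diameter']*1e3:.1f} mm, "
        f"collagen {last['collagen_fraction_mean']*100:.1f}%, "
        f"myocyte stress {last['sigma_myocyte_mean']/1e3:.1f} kPa"
    )
# Stage 1 returns to homeostasis in a slightly dilated, thinner-walled state;
# stage 2 plateaus above the set point and diverges (runaway growth).
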