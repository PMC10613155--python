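"""Prestress recovery of the in-vivo reference configuration (~1 minute).

Builds a coarse idealized LV, recovers the elastin prestretch field so the
loaded ventricle reproduces the imaged geometry at 120 mmHg, and reports the
convergence history and the transmural prestretch pattern.
"""

import numpy as np

from cardiogr import LVGeometry, LVModel, PrestressConfig, human_lv_mixture, run_prestress
from cardiogr.params import MMHG
from cardiogr.prestress import principal_prestretches

mix = human_lv_mixture()
model = LVModel.from_geometry(LVGeometry(), mix, target_elements=1200, order=1)
print(f"mesh: {model.mesh.n_elements} linear tets, {model.mesh.n_nodes} nodes")

rep = run_prestress(model, 120 * MMHG, PrestressConfig(eps_pre=5e-5, ramp_steps=10))
print(
    f"prestress converged={rep.converged} after {rep.iterations} iterations; "
    f"residual displacement {rep.final_displacement*1e3:.4f} mm"
)

lam1 = principal_prestretches(model.fields.G3D)[:, 0]
t = np.clip(model.disc.interpolate(model.mesh.node_t), 0, 1)
print(
    f"largest principal elastin prestretch: {lam1.max():.3f}; "
    f"endocardial mean {lam1[t < 0.3].mean():.3f} vs epicardial {lam1[t > 0.7].mean():.3f}"
)
# The loaded, prestretched ventricle reproduces the reference geometry to
# within the tolerance; elastin is most expanded toward the endocardium
# (resolved cleanly on quadratic meshes).
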