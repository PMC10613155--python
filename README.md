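# cardiogr

A homogenized constrained mixture model of cardiac growth and remodeling
(G&R), applied to an idealized truncated-prolate-spheroid left ventricle.

Pathological cardiac growth — hypertrophy under hypertension, fibrosis,
dilation toward heart failure — emerges from the turnover of the tissue's
constituents rather than from prescribed growth laws. This package models
the myocardium as a constrained mixture of cardiomyocytes, four collagen
fiber families and an elastin ground matrix that co-occupy every material
point and deform together, each carrying its own stress-free configuration.
It is written for computational biomechanics researchers who want to study
mechanobiological stability and the reversibility of cardiac G&R without a
bespoke C++ finite element stack: everything runs on numpy/scipy.

## Model

Each fiber constituent *i* stores a referential density ρ₀ⁱ and an inelastic
remodeling stretch λᵣⁱ, with the multiplicative split **F** = **F**ₑⁱ **F**ᵣⁱ.
Turnover drives both toward a homeostatic fiber Cauchy stress σₕⁱ:

- net mass production  ρ̇₀ⁱ = ρ₀ⁱ kⁱ (σⁱ − σₕⁱ)/σₕⁱ, Poisson degradation −ρ₀ⁱ/Tⁱ;
- remodeling  λ̇ᵣⁱ = [ρ̇₀ⁱ/ρ₀ⁱ + 1/Tⁱ] · λᵣⁱ/(2I₄ⁱ) · (∂σⁱ/∂I₄ⁱ)⁻¹ (σⁱ − σₕⁱ),
  whose linearization at frozen stretch is a Maxwell element relaxing with
  time constant ≈ Tⁱ (exactly Tⁱ for passive constituents; see
  `docs/methods.md` for the myocyte's motor-unit correction);
- growth through a volumetric penalty Ψ# = κ/2 (det **F** − ρ₀(s)/ρ₀(0))²
  that converts net mass change into volume change along the softest
  direction.

Fibers carry Fung exponential energies (tension only), myocytes add an
active tone with stretch-dependent activation, and elastin is a prestretched
isochoric neo-Hookean matrix whose prestretch field **G**³ᴰ is recovered
iteratively so the loaded ventricle reproduces the imaged reference
configuration. The quasi-static equilibrium couples the mixture stress with
basal omnidirectional springs, pericardial normal springs, and the follower
systolic pressure on the endocardium; it is discretized with linear or
quadratic tetrahedra and solved by Newton's method with backtracking.

A thin-walled spherical surrogate and a material-point driver exercise the
identical constitutive/G&R kernels for fast property studies.

## Worked example

Hypertension on a coarse finite element ventricle
(`examples/05_fem_hypertension.py`):

```text
baseline ready: prestress 274 iterations, residual 0.0100 mm
step to 140 mmHg: stable after 322 days; wall thickness 10.81 mm,
  endocardial diameter 39.9 mm, collagen 10.4%, myocyte stress 22.0 kPa
step to 180 mmHg: unstable after 148 days; wall thickness 10.74 mm,
  endocardial diameter 44.8 mm, collagen 11.3%, myocyte stress 27.5 kPa
```

A stage-1 step (120→140 mmHg) perturbs the myocyte stress away from its
22 kPa set point; G&R returns it to homeostasis in a slightly dilated,
thinner-walled, more fibrotic configuration — stable, eccentric remodeling.
The stage-2 step (180 mmHg) leaves the stress plateaued above the set point
and the deviation eventually grows for every constituent: runaway growth,
classified mechanobiologically unstable. Returning the pressure to baseline
after a stable stage-1 episode reverses the growth almost completely (the
geometry returns within a fraction of a percent of the reference).

Other examples: homeostatic calibration (`01`), Maxwell-analog stress
relaxation of a material point (`02`), the thin-wall surrogate (`03`),
prestress recovery with the transmural elastin prestretch pattern (`04`),
and a reduced stability map over the growth constant and pressure step
(`06`).

A thin CLI wraps the scenario layer:

```bash
cardiogr run examples/config_stage1.yaml
cardiogr prestress examples/config_stage1.yaml
cardiogr sweep examples/config_stage1.yaml --gains 0.05,0.2 --pressures 140:220:20
```

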