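# Methods

## Mixture model

The myocardium is a constrained mixture: at every material point a myocyte
family, four collagen fiber families and an elastin ground matrix co-exist,
deform with the same total deformation gradient **F**, and each carry their
own stress-free configuration. The mixture strain energy per unit reference
volume is the mass-weighted sum of constituent energies per unit mass plus a
volumetric penalty,

Ψ = Σᵢ ρ₀ⁱ(s) Wⁱ(**C**ₑⁱ) + κ/2 (J − ρ₀(s)/ρ₀(0))²,

and the first Piola–Kirchhoff stress is **P** = ∂Ψ/∂**F**. Fiber
constituents are quasi-1D: Wⁱ = aⁱ/(2bⁱ){exp[bⁱ(I₄ₑⁱ−1)²]−1} with
I₄ₑⁱ = (f₀ⁱ·**C**f₀ⁱ)/λᵣⁱ², excluded in compression (energy and derivative
zero for I₄ₑ < 1, a hard switch — the stress is continuous there). Elastin
is isochoric neo-Hookean, W = c₁(Ī₁−3), evaluated on the elastic deformation
**F G**³ᴰ including its symmetric, unit-determinant prestretch. The penalty
interprets |**F**| as det **F**; κ = 150 kPa ties the Jacobian to the
referential mass ratio so growth is realized as volume change along the
locally softest direction.

### Stress convention and calibration

Turnover is driven by a *constituent fiber Cauchy stress*. We use the
intensive convention

σⁱ = 2 ρ̂ I₄ₑⁱ ∂Wⁱ/∂I₄ₑⁱ (+ active term for myocytes), ρ̂ = ρ₀(s=0) = 1050 kg/m³,

i.e. the constituent's partial mixture Cauchy stress divided by its volume
fraction at constant true density; the set point is then purely
strain-driven. The myocyte active term is ξᵐ(s)·σ_act·f(λ_act) with
f = 1 − ((λ_max−λ_act)/(λ_max−λ₀))², clamped to [0, 1], and
ξᵐ(s) = ρ₀ᵐ(s)/ρ₀(0): the active energy is normalized by the *total*
mixture density, so the stress carries the (evolving) myocyte mass fraction.
The initial active stretch is calibrated once in closed form so that the
myocyte stress at its homeostatic elastic stretch 1.1 equals 22 kPa:
λ_act(0) = 0.9640511. The collagen set point under the same convention is
206.536 kPa at λ_h = 1.062; it is frozen as a regression constant in the
tests. The alternative mapping c₁ = aᵉ/2 for elastin is exposed as
`elastin_half_coefficient`.

### Active-stretch evolution

The active stretch evolves with ∂λ_act/∂λ = 1/λ. Two readings of λ are
implemented (`MixtureParams.active_reference`):

- `"total"` (default): λ is the total fiber stretch relative to the
  reference configuration, λ_act = λ_act(0) + ln λ. Active tone then
  ratchets permanently with dilation. This is the literal stated law and is
  the default because it reproduces the benchmark stability behavior of the
  3D ventricle (stage-1 hypertension stable, stage-2 unstable).
- `"elastic"`: λ is the elastic stretch relative to the constituent's
  evolving stress-free configuration, λ_act = λ_act(0) + ln(λₑ/λ_h); the two
  coincide under purely elastic loading, but turnover then re-adapts the
  tone toward its baseline (an adapting active reference configuration).

The choice matters for the thin-wall surrogate: its spherical wall couples
fiber stretch one-to-one to dilation, and under the `"total"` law the
active-tone ratchet dominates the stabilizing effect of a larger growth
gain, so the surrogate's stability boundary *decreases* with k·T; under
`"elastic"` it increases, as in the 3D model's map. Both behaviors are
exercised in the tests; quantitative stability-map claims belong to the FEM
path only.

## Turnover and remodeling

ρ̇₀ⁱ = ρ₀ⁱ kⁱ (σⁱ−σₕⁱ)/σₕⁱ with degradation −ρ₀ⁱ/Tⁱ (true production =
net − degradation). The remodeling stretch obeys
λ̇ᵣⁱ = [ρ̇₀ⁱ/ρ₀ⁱ + 1/Tⁱ]·λᵣⁱ/(2I₄ₑⁱ)·(∂σⁱ/∂I₄ₑⁱ)⁻¹·(σⁱ−σₕⁱ); its
linearization at frozen stretch relaxes stress deviations exponentially
with rate 1/Tⁱ for the passive constituents. For the myocyte the motor
unit scales with the evolving mass, which adds a slow counter-term: the
closed-form linearized rate is (1/Tᵐ)(1 − kᵐTᵐ σ_act,0/σₕᵐ) ≈ 1/10.75 per
day at the baseline calibration. The tests verify both constants to 1%.
The remodeling gradient **F**ᵣ = λᵣ f₀⊗f₀ + λᵣ^(−1/2)(**I**−f₀⊗f₀) is
isochoric by construction.

Degenerate compression: the passive stiffness ∂σ/∂I₄ₑ vanishes for slack
fibers, but its one-sided tension limit 2ρ̂a is finite. The simulation
kernels floor the remodeling stiffness at that limit so slack fibers
continue to shorten their natural configuration and re-engage; freezing
λ̇ᵣ instead lets slack myocytes atrophy irreversibly and destabilizes even
mild pressure steps. The scalar diagnostic `remodeling_rate` keeps the
strict contract (zero rate, with a warning) for a literal zero stiffness.
Elastin neither grows nor remodels.

Integration is forward Euler at Δt = min(Tⁱ)/20 = 0.5 day by default, with
an implicit trapezoidal alternative (fixed-point iterated) that the tests
require to agree within 0.1%. The local equations advance once per time
step, not per Newton iteration.

## Finite element ventricle

The wall between two coaxial truncated prolate spheroids (Table-constants
geometry: endocardial 46/19 mm, epicardial 55/30 mm semi-axes, truncated
13 mm above the equator) is meshed by a structured parametric grid split
into tetrahedra (Kuhn 6-tet decomposition, face-conforming across the
periodic seam; degenerate apex cells collapse to a pole). Quadratic
elements place mid-edge nodes through the exact geometry map, which makes
the meshed wall volume accurate to <0.1% at ~1000 elements; the meridional
grid contains both equatorial rings exactly, where the mid-cavity metrics
are measured (thickness = mean paired endo–epi node distance, diameter =
largest in-plane endocardial chord, cavity volume by divergence theorem
with a basal cap).

The transmural coordinate comes analytically from the mesh parametrization
(0 endocardium → 1 epicardium); the myocyte helix angle is linear in it,
+60° → −60° against the local circumferential direction, rotated in the
plane perpendicular to the transmural gradient. Collagen families lie in
the same wall plane at 0°, 90° and ±45° to the myocyte. Near the apex the
circumferential direction degenerates; affected Gauss points copy it from
the nearest well-defined point (cutoff 10⁻³ of the maximal in-plane
radius).

Boundary conditions follow the study setup: omnidirectional springs on the
base (c_base = 2.0 kPa/mm), reference-normal springs on the epicardium
(c_p = 0.2 kPa/mm), follower pressure p J **F**⁻ᵀ **N**₀ on the
endocardium. Assembly is total-Lagrangian with analytic consistent
tangents (verified against finite differences to ~10⁻¹⁰); Newton uses
backtracking line search and a sparse LU (minimum-degree on A+Aᵀ) solver.
The residual tolerance is 10⁻⁸ relative to the pressure-load scale.

## Prestress

Fibrillar constituents are placed at their homeostatic stretch via the
initial remodeling stretch λᵣ(0) = 1/λ_h; the elastin prestretch **G**³ᴰ
starts at identity and absorbs, after every equilibrium solve, the
isochoric part of the residual deformation through a polar decomposition
(symmetric factor, renormalized to unit determinant). Loads and fiber
prestretch ramp linearly over the first 10 iterations. The boundary springs
are prestressed alongside: after each iteration their rest state shifts by
the solved displacement, so at convergence they carry the pressure reaction
in the reference configuration (without this, the net endocardial pressure
force leaves a millimeter-scale rigid offset that no isochoric prestretch
can remove). Convergence is declared when the maximum nodal displacement
norm falls below ε_pre; activating G&R afterwards adds a drift of the same
order as ε_pre (checked as an order-of-magnitude bound). The transmural
pattern — largest principal elastin prestretch at the endocardium, maximum
near the basal endocardial ring — appears cleanly on quadratic meshes;
coarse linear meshes smear it.

## Scenarios and classification

A scenario starts from a prestressed baseline at 120 mmHg settled by 100
G&R steps, applies Heaviside pressure steps between two G&R steps with a
single static re-solve, and records per-step constituent stress statistics
(unweighted over Gauss points; volume weighting optional), mid-cavity
metrics and collagen mass fractions. A run is *stable* once
maxᵢ max_gp |σⁱ−σₕⁱ|/σₕⁱ ≤ 10⁻³, *unstable* when the per-constituent
maximum deviation increases for all remodeling constituents over 10
consecutive steps, *undecided* at the horizon (default 2000 days).
Classification begins only after the last scheduled pressure change, so
reversal protocols are not classified during their first phase. Everything
is deterministic (structured mesh, no random numbers).

## Problem sizes used by the tests

The test suite runs the 3D scenarios at a deliberately coarse setting:
~1500 linear tetrahedra, G&R step 2.5 days, prestress tolerance 0.01 mm —
about a minute per scenario. At this size all *qualitative* study results
reproduce: stage 1 (140 mmHg) is stable with thinning/dilation/collagen
gain, stage 2 (180 mmHg) is unstable, pressure steps ≤135 mmHg are stable
even at the weakest gain and ≥225 mmHg unstable even at the strongest, and
stage-1 reversal returns thickness and diameter within a fraction of a
percent of baseline. The *quantitative* stable endpoints are shallower than
the full-resolution study (e.g. stage-1 thickness 10.8 mm vs 9.5 mm,
diameter 40 mm vs 45 mm, collagen 10.4% vs 12%): the coarse linear mesh is
stiffer and sits farther from the stability boundary, so the stable drift
is smaller and the unstable growth clock faster; consequently an early
intervention at day 150 of stage 2 finds the coarse model already past
recovery. The corresponding acceptance tests assert the published values at
their published tolerances and are expected to fail at this problem size;
they pass only at the full study resolution (~4000 quadratic elements,
0.5-day steps), which takes hours on a workstation.

## Known limitations

- Single-phase quasi-static mechanics at the G&R timescale only; no cardiac
  cycle, hemodynamic adaptation, infarction or pericardial contact.
- The thin-wall surrogate has no transmural gradients or helix architecture
  and exaggerates the dilation–active-tone coupling (see above); it is for
  property tests, not quantitative prediction.
- The penalty formulation enforces constant spatial density only
  approximately (exactly in the κ → ∞ limit).
- Linear tetrahedra are usable for fast scans but are stiffer under the
  near-incompressible penalty; quadratic elements are the default for
  quantitative work.
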