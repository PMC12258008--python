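# Methods

This note documents the models, numerical choices and limitations behind
`scenariofree`. Nothing here states a result; every number a study produces
is computed by the test suite or by `scripts/acceptance.py`.

## Uncertainty model and scenarios

A scenario is a rigid isocenter shift (mm per axis), a range-error pair
`(c_abs, c_rel)` applied to radiological depths as
`rd' = rd̄ · c_rel + c_abs` (clamped at 0), a CT-phase index, and an
importance weight. Defaults: setup SD 2.25 mm per axis; range SD 1 mm
(absolute) and 3.5 % (relative); all five error coordinates independent
Gaussians, no correlation model.

Two sampling strategies build the training set:

* **random** — i.i.d. draws, uniform weights `1/n` (frequency already
  encodes importance);
* **worst-case** — a deterministic ±2σ grid: 26 setup shifts (all
  `{−2σ, 0, +2σ}³` combinations except all-zero), two simultaneous
  over-/under-shoot range scenarios (`c_abs = ±2σ_abs` with
  `c_rel = 1 ± 2σ_rel`), and the nominal scenario — 29 members. Weights are
  proportional to the product of the per-component Gaussian densities at the
  scenario coordinates, normalized over all 29 jointly; normalization
  constants cancel, so only the relative densities matter and the nominal
  scenario necessarily carries the largest weight.

Evaluation pools are random with a seed offset (+7919) from the training
seed so training and evaluation never share draws.

The sign convention follows the depth transform literally: `c_abs > 0`
*deepens* the water-equivalent depth, so a proton Bragg peak moves to a
shallower geometric depth (an undershoot). One `(c_abs, c_rel)` pair
applies to *all* beams of a scenario (range errors model patient-wide
stopping-power miscalibration, not per-field effects). 4D phases are
equidistant in time, hence uniformly weighted; 4D scenario sets reuse one
error set across phases by default, but any per-phase error set can be
supplied.

## Phantoms

`make_box_phantom` builds a homogeneous water box (default 120 mm cube at
3 mm spacing, 40³ voxels) with a centered cubic target whose relative
density is raised by 0.1 (a stand-in for raised HU; the exact contrast is
immaterial to the studies, it only makes the phantom mildly inhomogeneous)
and a cubic OAR offset distally along the 0° beam. This is a deliberately
scaled-down stand-in for clinical grids (~10⁷ voxels): it keeps every
experiment within minutes on one CPU while preserving the structure of the
problem (target coverage vs OAR sparing vs robustness).

The 4D phantom shifts the whole geometry rigidly by whole voxels along one
axis: phase `k` is displaced by `(k − (n−1)//2)·step`. For an odd phase
count the shifts are symmetric about zero; for an even count (e.g. the
10-phase default) they are off-center by one step — an exactly symmetric
even set is impossible with whole-voxel shifts. Whole-voxel motion keeps
per-phase structure masks in exact row correspondence (single-axis shifts
preserve flat-index order), which the 4D accumulation exploits.

Margins are Euclidean on voxel centers (isotropic mm margins, not
Chebyshev); the ITV is the voxelwise union of the per-phase CTVs in the
shared room frame, and the PTV adds a configurable margin (4 mm default).

## Dose engine

The pencil-beam kernel is this package's own analytic stand-in (clinical
engines are far richer; none is a dependency here). Beams are parallel;
the gantry angle rotates the ray direction in the axial plane. Per beamlet

    dose = depth_dose(rd') × exp(−r² / 2σ(rd')²),

with `σ(rd') = σ₀ + k·rd'` (defaults 3 mm + 0.03/mm), photon depth dose
`exp(−μ·rd')` (μ = 0.005/mm), proton depth dose a plateau (0.3 of peak,
rolled off by an erfc at the range) plus a Gaussian Bragg peak (σ = 7 mm)
at the beamlet's nominal range, times a constant RBE of 1.1 (photons 1.0).
Proton ranges are auto-spaced by one Bragg σ across the target's nominal
depth extent. The parameters were chosen once so that a two-field box plan
is solvable to a uniform target dose; they are all exposed in
`KernelParams`.

Radiological depth is a midpoint-rule line integral (96 samples) of the
trilinearly interpolated density from the grid entry plane to each voxel
center — accurate to about half a voxel, which is all the studies need.

Scenario application: the lateral beamlet-axis offset is continuous (no
voxel rounding), and the along-beam shift component offsets the depth
(`rd' = (rd̄ − shift·d)·c_rel + c_abs`). With both pieces, a whole-voxel
setup shift translates the dose cloud *exactly* on a homogeneous phantom —
the static-dose-cloud property the tests assert. The lateral truncation
window (3.5 σ at the nominal maximum depth) is computed from the nominal
depth map so the candidate voxel set is identical across scenarios of one
phase; entries below 1e-4 of the column maximum are dropped (pencil-beam
lateral truncation, bounds memory).

## Probabilistic quantities

`accumulate` streams `(D_s, π_s)` pairs once, holding a single scenario
matrix at a time: first moment as a running sparse sum, per-VOI second
moments `Σ π_s D_{s,v}ᵀ D_{s,v}` as dense symmetric blocks. Ω is formed
once at finalization (second moment minus outer product of the mean) rather
than by incremental subtraction, limiting cancellation; it is then
symmetrized. Quadratic forms clamp tiny negative rounding residues
(|value| ≤ 1e-8 · tr Ω · ‖x‖²) to zero and raise beyond that. E[D] stays
sparse (its size scales with voxels); each Ω_v is dense beamlets² —
mirroring the fact that Ω's size is independent of the voxel count.
Penalties are never folded into Ω, so one accumulation serves any penalty
tuning.

For 4D data the per-phase accumulators combine in two modes:

* **pooled** — raw moments summed across phases before forming Ω, so
  breathing motion contributes to the variance;
* **within_phase** — Ω formed per phase, then averaged with phase weights
  (within-phase error variance only).

These two fixed definitions are related by the law of total variance
(`Ω_pooled − Ω_within` = weighted covariance of phase-mean matrices); the
tests verify the identity on toys and on real dose matrices. Phase-varying
VOIs (the moving CTV) are handled by row-aligned per-phase index arrays.

## Optimization

Objectives (all normalized by structure voxel count): squared deviation,
squared overdose, mean-dose deviation (implemented as the squared deviation
of the structure mean, which is differentiable), a max-DVH objective
(excess voxels above the reference dose penalized coldest-first — the
cheapest voxels to push below the threshold), and the mean-variance term
`xᵀΩ_v x/|v|`. Constraints: mean-variance cap and expected mean-dose cap.

Three modes share one solver: scenario-free (objectives on `E[D]x` plus Ω
terms; one forward/adjoint E[D] product plus one Ω product per variance
term per evaluation), stochastic (scenario-weighted objective sum; one
forward/adjoint product per scenario), and nominal (single matrix,
margin-based structures). The solver is projected quasi-Newton (L-BFGS-B)
for `x ≥ 0`, initialized with a uniform fluence scaled to hit the target
prescription in the mean; inequality constraints use an augmented-
Lagrangian outer loop (penalty start `≈ f(x₀)/τ²`, tenfold increases,
multiplier updates) until every residual is ≤ 1e-3 of its threshold.
Non-convergence is a reported status, not an exception. The iteration
budget (1000) and tolerances (`ftol` 1e-12, `gtol` 1e-7) are deliberately
tight so that the two robust modes, which optimize numerically different
but mathematically identical functions in the validation study, land on
visually and gamma-identically equal plans.

The validation study adds a small identical L2 fluence regularizer (1e-7)
to both modes: it makes the convex least-squares problem's minimizer unique
(beamlets that barely influence any structure would otherwise be
undetermined), is mode-independent, and therefore preserves the exact
objective identity. Penalties where the studies need them are target 100 /
OAR 10, with the mean-variance penalty per structure equal to that
structure's least-squares penalty — the configuration in which the
scenario-free and stochastic objectives coincide term for term.

## Evaluation

Robustness analysis recomputes `D_s x` per evaluation scenario (matrices
built once per scenario and applied to all plans). Voxelwise SD uses the
weighted population variance (no Bessel correction), consistent with the
importance-weight formalism. DVH and SDVH are cumulative (volume fraction
with dose/SD ≥ axis value, computed over the full structure); DVH bands are
5–95 and 25–75 percentile envelopes over per-scenario DVHs with the
expected-dose DVH as the central line. 4D evaluation uses each scenario's
phase-specific structures for curves; expected dose and SD accumulate
voxelwise on the shared room-frame grid.

Gamma analysis is global: dose difference normalized to the stated % of the
*reference* maximum, voxels below the low-dose threshold (1 % of that
maximum) excluded, evaluated dose trilinearly interpolated on a sub-voxel
offset lattice (spacing / subsample factor, default 3) within a 3×DTA
search radius. Offsets beyond one DTA cannot produce a pass (the distance
term alone exceeds 1), so the pass/fail search terminates early.

Computational efficiency is reported as time per iteration (TPI) and its
ratio to the nominal plan (rTPI), plus *instrumented* forward/adjoint/Ω
product counts per objective evaluation — the counts, not wall times, carry
the scenario-count-independence claim in the tests.

## Study conditions and problem sizes

The acceptance studies run on the 40³ box with two proton fields (0°/90°,
7 mm beamlet lattice, ~700 beamlets), 9 random training scenarios and a
100-scenario evaluation pool — sizes chosen so each study completes in
minutes on one CPU while the matrices remain large enough for the
sparse/dense trade-offs to be real. The constrained study uses the
mean-variance caps 2.9×10⁻² and 2.9×10⁻³ Gy²; the sample-size study uses
nested pools (the first k of one seeded 100-scenario draw, k ∈ {5, 29, 50,
100}) so the sample-size effect is not confounded with draw-to-draw noise.

## Limitations

The dose engine is a toy: no heterogeneity lateral scaling, nuclear halo,
divergence, Monte Carlo transport, or buildup; phantom motion is rigid,
whole-voxel and single-axis; no DICOM import or deformable registration.
Passing tests therefore demonstrate the correctness of the probabilistic
machinery and the qualitative behavior of the algorithms (equivalence,
constraint activity, variance orderings), not clinical dosimetry. Minimax
and CVaR robust operators, analytical probabilistic modeling, low-rank Ω
compression and Pareto navigation are out of scope.
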