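# Methods

This note documents the models, numerical choices and design decisions
behind `aortauq`, and what the synthetic study conditions do and do not
establish about real patient-specific modelling.

## Constitutive model

The wall is an incompressible, isotropic 2nd-order Ogden solid in the
solver convention

    W(λ₁, λ₂, λ₃) = Σᵢ (2μᵢ/αᵢ²)(λ₁^αᵢ + λ₂^αᵢ + λ₃^αᵢ − 3),   λ₁λ₂λ₃ = 1,

chosen because fitted (μᵢ, αᵢ) pairs in this form are directly usable as
inputs to the major commercial FE solvers, where such simulations are
typically run. Principal Cauchy stress differences are
σⱼ − σₖ = Σᵢ (2μᵢ/αᵢ)(λⱼ^αᵢ − λₖ^αᵢ); incompressibility is enforced exactly
(no volumetric term), and anisotropy is deliberately omitted — aneurysmal
tissue loses much of its directional dependence, and the circumferential
and longitudinal test curves are therefore fitted jointly as two equibiaxial
records.

**Parameter validity.** Fitted parameter sets are screened before use. Two
predicates are exposed:

- `ground_state` (default): μ₁ + μ₂ > 0, i.e. positive initial shear
  stiffness. This is the default because the published nominal aneurysmal
  parameter set (μ₁ = 5.0, α₁ = 7.3, μ₂ = −0.4, α₂ = 18.8 MPa) satisfies it
  while violating the per-term condition below; a screen that rejects the
  nominal material would be self-defeating.
- `strict_hill`: additionally μ₁α₁ > 0 and μ₂α₂ > 0 (per-term monotone
  stability). Retained as an option; which predicate a given FE workflow
  intends is ambiguous in practice, so both are implemented and neither is
  asserted as canonical.

**Fitting.** Trust-region nonlinear least squares (box bounds spanning the
epistemic ranges with margin, tolerances 1e-15, 2000 evaluations) with a
seeded 10-start cloud around the initial guess; the best validity-respecting
solution wins on cost, and a run with no such solution is returned flagged,
never silently. The reported RMSE is recomputed from the returned residual
vector, independent of optimizer internals. Near α = 0 the stress terms are
singular; |α| is floored at 1e-8 inside residuals. Note that when α₁ ≈ α₂
the two terms are collinear and only the fitted *curve* is identifiable,
not the (μ, α) split; parameter-recovery guarantees apply to materials with
separated exponents (distinct toe/stiffening regimes), which is what the
test population draws.

## Membrane vessel model

The FE stand-in is a quasi-static thin-walled membrane cylinder: unloaded
mid-wall radius R0 (mm), unloaded thickness s (mm), prescribed axial
stretch λ_z (default 1.0 — imaging-derived stretch/twist boundary
conditions are outside scope). Traction-free radial stress gives

    σ_θ(λ) = Σᵢ (2μᵢ/αᵢ)(λ^αᵢ − (λ λ_z)^(−αᵢ)),
    P = σ_θ(λ_θ) · s / (λ_θ² λ_z R0),

solved for λ_θ by a 601-point grid scan for the first sign change on
λ_θ ∈ [1, 3] followed by Brent refinement (stretch tolerance three decades
below the 1e-10 MPa residual tolerance, so the equilibrium residual at
converged solutions is below 1e-10 MPa even for supra-stiff materials). No
bracket expansion beyond λ_θ = 3 is attempted: distension beyond 3× is the
membrane analog of an exploded explicit-FE run, and such states are flagged
failures whose rows are dropped from the plan, mirroring how failed FE
simulations are excluded from surrogate training. Rows with physically
inconsistent sampled hemodynamics (Pdias ≥ Psys, possible because the
published pressure bounds overlap) are flagged failures for the same
reason.

**Units:** mm–MPa–s internally; mmHg→MPa factor 1.333224e-4, stated once in
`aortauq.units`.

**Geometry anchoring and diameter convention.** Two constructions are
supported. With a fixed `R0` the membrane inflates from a given unloaded
radius. The default pipeline construction instead anchors to an *imaged
diastolic mid-wall diameter*: per material sample, R0 is solved (Brent, on
R0) so that inflation at diastolic pressure reproduces the imaged diameter
— the membrane analog of recovering the zero-pressure configuration from
diastolic CTA before simulating the cycle. The reported loaded diameter is
by default the *lumen* (inner) diameter, 2λ_θR0 − s/(λ_θλ_z), which is what
CTA lumen segmentation measures; the mid-wall convention is available.
These two choices matter: with a fixed unloaded radius and mid-wall output,
the 9-D sensitivity of diameter is overwhelmingly dominated by μ₁ (membrane
compliance ∝ 1/(μ₁+μ₂) over a range spanning three decades), whereas
diastolic anchoring cancels the bulk of the pure-stiffness effect (as the
imaging-anchored FE workflow does) and the lumen convention adds the direct
geometric thickness pathway. Under the anchored/lumen construction the
pipeline reproduces the qualitative sensitivity structure expected of
imaging-anchored ATAA models — wall thickness ranks first for the diameter
output and thickness + systolic pressure dominate wall stress, with heart
rate, diastolic pressure and α₁ marginal.

**Hemodynamic coupling.** How transaortic velocity V and heart rate HR
enter a structural-only model is not defined by the physics; they enter
here through an explicitly synthetic effective peak pressure

    P_eff = Psys·(1 + c_V·(V − V_nom)/V_nom)
            + c_HR·((HR − HR_nom)/HR_nom)·(Psys − Pdias),

with defaults c_V = 0.02, c_HR = 0.01 (V_nom = 1.3 m/s, HR_nom = 70 bpm)
chosen small so HR and V sensitivities stay marginal, consistent with the
expected structure. The coefficients are logged in every report.

**Pressure waveform.** A normalized analytic pulse (squared half-sine
upstroke peaking at 30 % of the cycle, exponential diastolic decay reaching
0 at cycle end) is scaled affinely to (Pdias, Psys) and in duration to
60/HR s. The quasi-static solve uses only its peak; the waveform exists so
the discretization-convergence study has a real discretization to vary (the
sampled peak underestimates Psys at coarse sampling and converges
quadratically).

## Study conditions (synthetic cohort)

Synthetic patients are pure functions of (configuration, seed). True inputs
are truncated-Normal draws centered at the nominal values with
sd = (UB − LB)/4 — so "true" patients resemble the nominal column while the
DOE/qMC stages span the full box — redrawn until the material passes the
validity screen and the membrane converges. The imaged diastolic mid-wall
diameter is uniform on 42–55 mm (the aneurysm size range of the clinical
test sample this emulates). The comparator is a triplicate
Normal(true diameter, 0.625 mm) measurement; 0.625 mm is the scanner's
through-plane voxel size, taken as one standard deviation (whether it is a
standard deviation or a hard half-voxel bound is not knowable from the
source; the Normal-sd reading matches how the comparator CDF is used).

The one published bound-table quirk — the α₂ nominal (18.8) lying outside
its printed (−98.8, 14.6) bounds — is preserved as printed: bounds are
canonicalized to [min, max] and a warning (not an error) is raised.

What passing tests on this cohort do **not** show: anything about
segmentation fidelity, 3-D geometry effects, anisotropy, dynamic inertia or
pressure-wave propagation, inter-subject input correlations (inputs are
sampled independently), or the specific numeric results of any real-patient
FE study.

## Design of experiments

"9 × 7 random combinations" is implemented as 7 Latin hypercube samples per
variable in 9-D — 63 rows total, one point per column stratum — with plain
random pairing (a discrepancy-optimized plan is available via scipy's
`optimization` options). Material-invalid rows are filtered before
simulation with a full dropped-row log; simulation failures are dropped
after, so the surrogate trains only on converged runs.

## Surrogate

Anisotropic squared-exponential kernel with signal variance and a fixed
nugget of 1e-8, inputs standardized, output centered and scaled (the
scaling is owned by the package, not sklearn's per-fit normalization, so
leave-one-out folds share the full-data normalization and the frozen-kernel
literal LOO agrees with the closed-form identity to machine precision).
Hyperparameters maximize the log marginal likelihood with a seeded 5-start
multi-start. LOO is a literal n-fold refit; re-optimizing hyperparameters
per fold is available (`refit_hyperparameters=True`) but off by default for
speed — both honor "built from the remaining n−1 runs". R² is the
coefficient of determination 1 − SSE/SST of the LOO predictions; MRE is
mean(|eᵢ|/|yᵢ|)·100 with zero-valued outputs excluded under a warning.

## Uncertainty quantification and validation

Propagation uses scrambled Sobol sequences scaled to the bounds (10,000
draws by default). Total-effect indices use Saltelli A/B/A_B^(i) matrices
and the Jansen estimator (lower variance than the Sobol'–Homma–Saltelli
form), base_n = 1024 ⇒ (9+2)·1024 surrogate evaluations, a separate sample
from the 10,000-draw output-distribution sample. TEIs are reported as raw
STᵢ·100 (they need not sum to 100) in Pareto order, with association signs
from Spearman rank correlations on the qMC sample (|ρ| < 0.01 →
indeterminate).

The area metric integrates |F_model − F_comparator| exactly: the empirical
step CDF is integrated piecewise against the Normal comparator CDF with the
Normal-CDF antiderivative, splitting each step interval at its level
crossing, over [min − 8σ, max + 8σ] extended to cover the comparator mean.
The percentage form divides by the comparator mean diameter — the source
wording ("percentage difference") never defines the denominator, so this is
a declared, configurable choice that makes the ≤ 5 % severity rule a
fraction of aneurysm size. Wall-stress uncertainty is summarized by a
Gaussian KDE (Silverman bandwidth), its mode on a 512-point grid, and the
2.5–97.5 % interval.

## Verification

RE = 100·|test − reference|/|reference|, criterion RE < 1 %. The membrane
model has no mesh; the discretization-error analog is the waveform sampling
count and the solver-setting analog is the root-finder tolerance, each
studied against the finest/tightest reference with the coarsest passing
level selected (a study with no passing level is returned flagged). Code
verification inflates a supra-stiff cylinder (μ₁ = 1000 MPa, R0 = 10 mm,
s = 2 mm, 120 mmHg) and compares against the analytic thin-wall *hoop*
stress P·r/t ≈ 80 kPa, the closed-cylinder solution matching the
implemented geometry; the spherical-form value P·r/(2t) ≈ 40 kPa is
computed and reported alongside, since published verification tables are
sometimes stated in that convention with values (e.g. 31.6 kPa) that the
printed inputs do not reproduce — neither convention's tabulated value is
treated as ground truth here.

## Pipeline and determinism

All randomness flows through named seeds in `PipelineConfig`
(cohort/lhs/gp/qmc/sensitivity/comparator); no global RNG state. Identical
configuration produces a byte-identical JSON report. Stage failures are
recorded per stage in the report (`stages_failed`) rather than aborting the
run. Default problem sizes — 63-run plans, 10,000 qMC draws, base_n = 1024,
one synthetic patient — keep a full credibility run under ~10 s on one CPU;
the test suite uses smaller qMC/sensitivity samples (2,000 / 256) for its
pipeline round-trips, which is ample for the qualitative checks made there.

## Known limitations

- The membrane model is 0-D in space: no bending, no curvature variation,
  no contact, uniform pressure. Verification "mesh" analogs are genuinely
  different error sources from FE discretization error.
- Thickness is uniform; real aneurysm walls vary regionally.
- The HR/V coupling is synthetic by construction and only qualitatively
  reasonable.
- Sobol indices are estimated for independent uniform inputs on the box;
  correlated epistemic inputs would need a different estimator.
- The area metric becomes insensitive to variance differences when the two
  CDFs do not cross — a known property of the metric itself.
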