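# Methods

## Model

`cmmfit` implements a constrained mixture model (CMM) of the arterial wall.
The wall is a mixture of three load-bearing constituents — elastin (e),
collagen (c) and smooth muscle (m) — with mass fractions φ^α that sum to
one. All constituents deform with the mixture, but each is deposited into
the tissue at the *in-vivo* configuration (pressurized, axially tethered)
carrying its own prestretch from its stress-free natural state. With the
in-vivo state as reference (mixture deformation gradient F = I there), the
constituent gradient is

    F^α = F G^α,

where G^α is the symmetric, unimodular deposition-stretch tensor. Elastin
is prestretched biaxially, G^e = diag(1/(G_θ^e G_z^e), G_θ^e, G_z^e) in the
cylindrical basis (r, θ, z); collagen consists of two mirror-symmetric
fiber families at ±β from the longitudinal axis in the θ–z plane, each with
G^ci = G^c d^ci⊗d^ci + (G^c)^(-1/2)(I − d^ci⊗d^ci); smooth muscle is
purely circumferential with the analogous G^m.

The strain energy is the mass-fraction-weighted sum of an isochoric part
per constituent plus a volumetric penalty:

    W = φ^e (c^e/2)(Ī₁^e − 3)
      + φ^c Σ_{i=4,6} k₁^c/(2k₂^c) [exp(k₂^c (Ī_i^c − 1)²) − 1]
      + φ^m k₁^m/(2k₂^m) [exp(k₂^m (Ī₄^m − 1)²) − 1]
      + (κ/2)((J² − 1)/2 − ln J),

with invariants computed from the isochoric constituent tensors
C̄^α = J^(−2/3) F^αᵀ F^α. Fiber terms carry load only in tension
(pseudoinvariant above one), applied independently per family. The Cauchy
stress follows from σ = (1/J) F (2∂W/∂C) Fᵀ.

Two stress modes exist. The `penalty` mode (κ = 500 c^e by default) is the
nearly incompressible formulation and is used for energy–stress consistency
checks. The semi-analytic solvers use the `incompressible` mode: the stress
is evaluated on the unimodular part of F and the hydrostatic reaction
pressure is resolved from traction boundary conditions. When k₂ < 1e−8 the
fiber energy switches to its analytic limit (k₁/2)(Ī₄ − 1)² to avoid 0/0;
the identified smooth-muscle k₂^m = 0.024 sits near this regime.

## Mechanical-state solvers

All solved configurations belong to the incompressible axisymmetric family
r(R) = √(r_i² + (R² − R_in²)/λ_z) with F = diag(dr/dR, r/R, λ_z); for the
radially cut ring the circumferential entry acquires the sector ratio k
(opened central angle over 2π). Because the two collagen families are
mirror images, the stress is diagonal in (r, θ, z) everywhere, and a
vectorized diagonal fast path evaluates the extra stress across the wall.

* **Inflation–extension.** Radial equilibrium integrated across the wall
  gives p = ∫(σ_θθ − σ_rr)/r dr; the reduced axial force
  π∫(2σ_zz − σ_θθ − σ_rr) r dr is pressure-invariant and vanishes for a
  free-floating segment. Fixed axial stretch leaves one unknown (r_i,
  bracketed bisection/Brent); a zero-force condition adds λ_z (2-D Powell
  hybrid with warm-start guesses).
* **Unloading.** p = 0 plus zero axial force yields the ex-vivo state; the
  release gradient F_release is the thickness average of the pointwise
  diagonal gradient (15 uniform radial samples, mean ± SEM). The
  physiological axial stretch is reported as in-vivo length over ex-vivo
  length (reciprocal of the unloading stretch).
* **Ring opening.** The uniform-sector family cannot satisfy pointwise
  equilibrium, so three integral release conditions are imposed: zero
  radial-traction residual across the wall, zero net axial force, and zero
  bending moment of the circumferential stress across the cut (with σ_rr
  reconstructed from the radial equilibrium ODE and a traction-free outer
  face; the zero-net-circumferential-force condition is then satisfied
  identically). These are the stationarity conditions of the total elastic
  energy over the same family: a Nelder–Mead energy minimization agrees
  with the root solve to ~2 × 10⁻⁶ degrees and is kept as a cross-check
  test. The root is tracked by an adaptive homotopy from the uncut ring
  (k = 1), which keeps it on the branch continuously connected to the
  closed state. The opening angle uses the cut-face convention
  α = 180°(1 − k); k > 1 (overlapping ring) is admitted.
* **Quadrature.** 64-point Gauss–Legendre for pressure/force integrals; the
  ring-opening conditions use an 801-point uniform grid because the σ_rr
  reconstruction needs cumulative integration. Both give α to seven
  significant digits.
* **Uniaxial strip.** The constituent gradient composes the uniaxial
  stretch with the flattening (≈ identity), opening and release history:
  F^i = F_uniax F_flatten F_opening F_release G^i, with the history reduced
  to thickness-averaged diagonal tensors (their through-wall variation is
  small — SEM ≤ 0.03). The two transverse stresses vanish; with exact
  incompressibility of the mixture deformation this leaves one unknown
  lateral stretch, solved by bracketed bisection (the residual is strictly
  monotone) with a warm-started Newton fast path.

### In-vivo equilibrium and the `equilibrated_reference` option

With the printed scalar deposition stretches applied uniformly on the
in-vivo snapshot, the in-vivo state supports ≈ 5.2 kPa, not the 10 kPa
diastolic pressure: a uniform-prestretch state cannot pointwise equilibrate
a transmural pressure. The deposition procedure that builds the prestressed
state (pressurize, then deposit constituents so that the imaged geometry is
recovered) implies a slightly different reference. The
`equilibrated_reference=True` option reproduces it: an incompressible
radial relabeling of the reference annulus (fixed length) is solved such
that the imaged in-vivo geometry is in radial equilibrium at diastolic
pressure. The opening angle is invariant to this relabeling (verified
numerically — the sector equilibrium depends only on the constituent
natural states), while the unloading predictions shift by a few percent.
The default (`False`) deposits directly on the in-vivo snapshot, which
matches the published unloading ratios more closely and is used everywhere
except the equilibrium-preservation check.

## Inverse identification

Stage 1 fits the six material parameters mp = (c^e, k₁^c, k₂^c, β, k₁^m,
k₂^m) to circumferential and longitudinal uniaxial Cauchy stress–stretch
curves with the objective

    f = J(σ_circ, σ̂_circ) + J(σ_long, σ̂_long),
    J(y, ŷ) = (1/n) Σ (y − ŷ)² / max(y),

holding ds and the release/opening kinematics fixed. Stage 2 fits the four
deposition stretches ds to geometry targets with g = Σ (y − ŷ)², the
default target set being (d_out^invivo, d_in^exvivo, d_out^exvivo, λ_z);
a variant replaces the ex-vivo inner diameter with the in-vivo one. The
in-vivo prediction comes from inflation at diastolic pressure and fixed
length (a geometry-preservation residual), the ex-vivo predictions from the
unloading solve. The opening angle is deliberately *not* part of any
objective; it is predicted post-hoc as an external consistency check. The
integrated procedure alternates the stages, updating (ds, F_release,
F_opening) between iterations, and stops when every material parameter
changes by less than 5% (configurable) between iterations; ds changes are
tracked but not gated.

All minimizations are Levenberg–Marquardt (lmfit/MINPACK) with
finite-difference Jacobians (relative step 1e−6), cost/parameter tolerances
1e−8, moduli log-parameterized for positivity, β ∈ (0°, 90°), and ds boxed
to [0.9, 2.0].

### Identifiability and the joint pre-fit

Two structural properties of this inverse problem shape the implementation:

1. **The stage-2 objective is rank-deficient.** Under incompressible
   kinematics the ex-vivo inner diameter is a deterministic function of the
   ex-vivo outer diameter and the axial stretch (wall-area conservation),
   and likewise the in-vivo inner diameter of the outer one at fixed
   length. Either 4-target set therefore contains only three independent
   equations for four unknowns: the exact minimizers of g form a
   one-dimensional family (numerically confirmed — distinct exact roots
   exist at the same mp). The deposition stretches are identifiable only
   *jointly* with the curves.
2. **The stage-1 landscape is multimodal.** Single-start LM from
   literature-informed values (c^e = 30 kPa, k₁ = 30 kPa, k₂ = 1, β = 40°)
   reliably lands in a local minimum (collagen/muscle stiffness trades,
   β → 0 traps) even when ds and the kinematics are held at the generating
   values; seeded random restarts reliably find the global minimum. Stage-1
   fits therefore default to six seeded starts with best-cost selection and
   an early exit on (numerically) exact fits.

Because of (1) and (2), the plain alternation started from identity cannot
be expected to recover generating parameters: it has no force driving the
curve misfit down along the flat geometry direction. `run_integrated`
therefore begins (by default; `joint_prefit=False` disables it) with a
seeded multi-start Levenberg–Marquardt fit of all ten parameters against
the combined residual — both curves plus the geometry targets. The
exploration round recomputes the release gradient from the unloading solve
at every trial point while freezing the opening gradient at identity
(cheap and smooth); the few distinct best optima are then refit with the
fully self-consistent residual, in which the ring-opening solve runs at
every trial point (warm-started from the previous evaluation), so the
final comparison is made on one well-defined objective. The lowest-cost
refined optimum seeds the alternation, which polishes and verifies it
under the 5% stop rule. On noise-free synthetic data this recovers all ten
generating parameters to machine precision (the joint residual is exactly
zero at truth); the alternation then terminates in two iterations.

A numerical caveat worth recording: warm-start caches inside a residual
must be converged well below the optimizer's finite-difference step, or
the evaluation noise they introduce corrupts the FD Jacobians and stalls
the LM iterations — the transverse-stretch solve therefore accepts a
warm-started solution only below 1e−9 kPa residual.

## Synthetic data

The generator emulates the measurement suite of a newborn-lamb descending
thoracic aorta: J-shaped uniaxial curves in both directions (default grid
λ ∈ [1.0, 1.6], 30 points per direction — the physiological-to-
supraphysiological range of such tests) and an in-vivo/ex-vivo geometry
pair, all produced by forward simulation from a known parameter set. The
curves use the release/opening kinematics computed by the solvers (not
identity), and the geometry targets are the model's own predictions, so the
generating parameters are an exact optimum of the inverse problem at zero
noise. Noise is multiplicative Gaussian on stresses (heteroscedastic, as
for load-cell data; an additive option exists); geometry targets stay
noiseless. Fixed seeds give byte-identical output.

What the generator does *not* emulate: anatomical taper and bending of a
real aorta, layer-specific (media/adventitia) structure, viscoelastic
hysteresis and preconditioning of uniaxial tests, measurement error in the
geometry, or inconsistency between model family and tissue. Passing
recovery tests therefore demonstrate the correctness and identifiability of
the inverse machinery under the model's own assumptions, not robustness to
model misfit in real data.

The bundled reference record (`lamb_aorta_fixture`) carries the in-vivo
geometry (outer diameter 10.31 mm, inner 8.16 mm, length 0.2 mm), diastolic
pressure 10 kPa, literature mass fractions (0.5/0.2/0.3), and the
identified material parameters and deposition stretches of the lamb-aorta
study.

## Sensitivity study

Grid sweeps map mass fractions (φ_e ∈ [0.2, 0.6], φ_c ∈ [0.1, 0.3], φ_m
the remainder) and deposition stretches (G_θ^e ∈ [1.00, 1.20], G_z^e ∈
[1.05, 1.50], G_m ∈ [1.15, 1.68], G^c fixed at 1.10) to the opening angle
and the physiological axial stretch, one unload + ring-opening pipeline run
per grid point (defaults: 6 points per deposition axis, 5×5 for mass
fractions). Failures are recorded per point, never fatal; inadmissible
compositions (φ_m < 0) are skipped. Output is a tidy CSV; plotting is left
to the user.

## Monte-Carlo noise study

The recovery-under-noise experiment (`monte_carlo_recovery`, also run by
the acceptance test suite) uses 2% multiplicative stress noise and 20
seeded replicates of the same synthetic specimen. Following standard
bootstrap-refit practice, a reference estimate is first identified from
the pooled (replicate-averaged) curves with a thorough multi-start fit;
every replicate is then refit warm-started from that reference, so each
replicate estimate is a converged optimum of its own data while the
expensive global search is done once. The reported statistic is the median
relative error of the elastin modulus c^e across replicates (measured:
≈ 6% at 2% noise, all replicates < 17%; the whole study runs in about two
minutes).

## Numerical choices and edge cases

* Tension–compression switch on the *isochoric* pseudoinvariant (Ī₄ ≥ 1),
  per family — consistent with the isochoric invariants used in the
  energies.
* Exponent clamping at 500 in the fiber exponential guards LM excursions;
  moduli are bounded to [1e−3, 1e6] kPa inside fits.
* The unloading/inflation root solves fall back to multiple initial
  guesses; trial states that cannot be solved return a large finite
  residual to the optimizer rather than raising.
* Degenerate inputs: identity deposition stretches reproduce the reference
  geometry exactly (fixed-point tests at 1e−8); a stress-free ring stays
  closed (α = 0).
* The ring-opening homotopy halves its step on failure and stalls out with
  a diagnostic below step 1e−3.

## Known limitations

* Single-layer wall with homogenized parameters; no media/adventitia split.
* Exact incompressibility (the penalty mode exists only for constitutive
  checks); volumetric compliance of the nearly incompressible formulation
  is absent, which contributes percent-level differences from
  finite-element realizations of the same model.
* The uniform-sector ring opening ignores warping and end effects of a
  dynamic release simulation.
* No growth-and-remodeling mass turnover: the deposition stretches are
  snapshots, not evolving fields.
* Identified k₂ values near zero make (k₁, k₂) pairs sloppy; with noisy
  curves the muscle pair is recovered with large relative spread even when
  c^e is accurate.
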