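# Methods

## Constitutive model

The package models uniaxial deformation of brush-like elastomer networks
with a two-parameter equation of state for true stress,

σ(λ) = (E/9)(λ² − λ⁻¹)[1 + 2(1 − βI₁/3)⁻²],  I₁ = λ² + 2/λ,

with structural modulus E (kPa) and firmness β ∈ (0, 1). The model
assumes incompressibility (engineering stress converts as σ_true =
λ·σ_eng; every curve declares which stress kind it carries, and the
conversion is always explicit), quasi-static loading, and a uniform
network. Stress diverges at the singular elongation λ_sing where
βI₁/3 → 1; λ_sing is found by bisection on [1, 10/√β] to 1e−10, which is
simpler and no slower at this problem size than closed-form cubic roots.
A numerical check (dense β grid) confirms λ_sing ≥ β^(−1/2), so the
theoretical break always precedes the singularity. Compression (λ < 1)
is admitted with negative stress and the same denominator guard.

Derived quantities: Young's modulus E₀ = (E/3)(1 + 2/(1−β)²) (the λ→1
slope, verified numerically to 1e−6 relative), and theoretical
elongation at break λ_max = β^(−1/2). β = 0 is an explicit
non-stiffening limit in which the model reduces to (E/3)(λ² − λ⁻¹).

Units: stress in kPa on the entire tensile surface; rheology moduli in
Pa, matching instrument conventions for each record kind.

## Parameter estimation

`fit_constitutive` minimizes the residual between model and measured
true stress by bounded trust-region least squares (lmfit front end over
`scipy.optimize.least_squares`), with E > 0 and β ∈ (1e−6, 1−1e−6),
parameter-step tolerance 1e−10, and an evaluation budget equivalent to
500 iterations. Non-convergence is flagged on the result, never raised.

Residual weighting is uniform on true stress by default; optional
relative weighting (1/max(|σᵢ|, 0.1% of peak)) is recorded in the
result. On exact-model data the two agree to better than 1e−6 relative.

If an iterate pushes a data point to or past its singular elongation,
the stiffening denominator is passed through a smooth positive floor,
½(D + √(D² + δ²)) with δ = 1e−6: the residual becomes very large but
stays finite and C¹, so the optimizer backs away instead of crashing.

Starting values come from curve geometry: the small-strain slope over
the lowest-strain 20% of points (≥ 3) estimates E₀; β starts at
1/λ_last² clamped to [0.01, 0.9]; E follows by inverting the E₀
relation. A degenerate (non-positive-slope) toe region falls back to the
global secant. λ_max,exp is defined as the last recorded λ (the curve is
assumed truncated at rupture); no extrapolation is attempted.

Reference-table comparisons round half-up to one decimal, the table's
printed precision. Recomputing E₀ from printed (E, β) reproduces five
rows exactly at one decimal; the remaining rows differ by up to
0.24 kPa, consistent with the inputs themselves being rounded to their
printed digits, so those rows are checked to ±0.3 kPa. Two printed
elongation-at-break cells are inconsistent with one-decimal rounding of
β^(−1/2) (F:M 2:1 and 4:1) and are excluded from the exact-reproduction
check.

## Gel-point detection

The detector works on d(t) = log G′ − log G″ — log space because both
moduli traverse decades during cure — and takes the first *sustained*
sign change: d must stay positive for min(3, remaining) consecutive
samples, so single-sample flickers are skipped (and counted in
`n_crossings`). t_gel is linear interpolation of d against linear time
inside the bracketing pair; the crossover modulus is interpolated in log
space at t_gel. Loss-dominated and storage-dominated sweeps raise
distinct errors (still-liquid vs already-solid). No smoothing by
default; a 3-point running median is available for noisy sweeps.
Temperatures are kelvin internally; file metadata is °C.

Curing-time trends across a covariate (stoichiometric ratio, catalyst
level, temperature) are summarized by two equally supported regressions
— log t_gel vs log covariate, or log t_gel vs 1/T — since no functional
form is canonical; at least three distinct covariate values are
required.

## Texture profile analysis

Baseline is the median of pre-contact samples; contact threshold is 1%
of the global baseline-corrected peak. A cycle is a maximal
above-threshold run extended by one boundary sample each side (so traces
touching baseline exactly integrate without truncation); exactly two
cycles are required. Each cycle splits at its force peak. Metrics use
trapezoidal force–time areas — the time basis, matching the force–time
protocol convention:

* cohesiveness = (A2_down + A2_up)/(A1_down + A1_up),
* resilience = A1_up/A1_down,
* springiness = second-cycle over first-cycle contact-to-peak time
  (time-based; a displacement-based variant exists in instrument
  software but is not implemented).

Trapezoidal integration is exact on piecewise-linear signals, so the
constructed test traces recover their ground-truth metrics to rounding.
All metrics are invariant to positive force rescaling and time shifts.

## Scaling-law calibration and inverse design

The scaling law E = C·β/(1 + n_sc)^(3/2) is calibrated as a least-squares
slope **through the origin** (the proportional theoretical form has no
intercept) of E against β/(1 + n_sc)^(3/2); Pearson r and residuals are
reported. The analytic prefactor 3k_BT·l^(3/2)/v^(3/2) is available when
a monomer volume v is supplied (l defaults to 0.25 nm, the brush
backbone monomer length), but no established v exists for this
chemistry, so calibrated mode is the default.

No closed form links n_x to β, so the reference rows act as empirical
anchors, interpolated log-linearly in n_x within each n_sc family
(extrapolations are flagged). Candidate architectures are scored by the
root-mean-square of the relative errors of the anchored (E₀, β)
prediction against the target; the calibrated scaling law and the
self-consistent β solving the E₀-scaling coupling (damped fixed point,
damping 0.5, 100 iterations, tolerance 1e−10) are reported as
diagnostics per grid point. Scoring on the empirical anchors rather than
through the scaling law is deliberate: reference formulations scatter
around the law by factors up to ~2.8, and anchored scoring guarantees
that a target equal to a reference row's own mechanics retrieves that
row's architecture. An infeasible target yields an empty candidate list
with per-grid-point diagnostics, not an error.

Tissue matching ranks candidate parameter pairs by RMS relative
deviation from a supplied tissue curve over its λ > 1 range; candidates
whose extensibility the tissue exceeds receive large finite distances
via the smooth-floor model evaluation.

## Synthetic data

The generators define the conditions under which the pipeline is
validated:

* **Tensile**: exact equation-of-state evaluation on a uniform λ grid
  from 1 to β^(−1/2) (the theoretical break, where real specimens
  rupture — not the singularity), 60 points by default. Multiplicative
  Gaussian noise is the default noisy mode (load-cell error scales with
  load), 2% relative in the recovery studies — a conventional instrument
  figure, as no measured noise magnitude is available.
* **Rheology**: Hill-type growth for both moduli with shape exponent 2
  and plateaus G′_∞ = 10 kPa ≫ G″_∞ = 1 kPa (typical cured-elastomer
  contrast); the half-saturation time is set in closed form so the
  curves cross exactly at the requested t_gel, and the construction is
  re-verified at generation time. Additive noise mimics the early-time
  instrument floor.
* **TPA**: piecewise-linear two-cycle triangles whose areas equal the
  requested values exactly, with zero-force dwells flanking each cycle.
* The packaged reference table ships verbatim as CSV (11 formulations).
* A weakly strain-stiffening tissue stand-in is generated from a target
  (E₀, β), since real tissue curves are user-supplied tables.

Noise flows only through a seeded generator (seed mandatory whenever
noise is requested); equal specs are bit-identical. What these
generators do **not** emulate: viscoelastic relaxation and rate
dependence in tensile curves, cure-kinetics chemistry (the sweep shape
is phenomenological), adhesion/stickiness tails in TPA unloading, and
instrument drift. Passing recovery tests therefore demonstrates
correctness of the estimators under the model's own assumptions, not
robustness to every artifact of real instrument data.

## Problem sizes

The default validation scales are 60-point tensile curves, a factorial
(3 moduli × 4 firmness values) noiseless recovery sweep, 200 noisy
replicates at one reference parameter set, 100-point cure sweeps at
three decades of t_gel, and 25-sample-per-ramp TPA traces — desk-scale
runs chosen so the whole suite completes in seconds while exercising
every code path.

## Known limitations

* Uniaxial tension/compression only; no multiaxial or finite-element
  use of the constitutive law.
* No viscoelastic fitting; curves are assumed quasi-static and
  truncated at rupture (no automatic break detection).
* The β(n_x) anchor interpolation is empirical and only as good as the
  reference rows in the relevant n_sc family; extrapolations are
  flagged but unvalidated.
* Printed-precision reference inputs limit derived-column reproduction
  to the documented ±0.3 kPa band on some rows.
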