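# Methods

This note records the models implemented by `micelkin`, the estimator and
numerical choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Loading and encapsulation efficiencies

For a feed of `P` mg polymer and `A` mg drug, with an assayed content of
`c` mg drug per gram of recovered micelle powder, the powder is composed of
polymer + drug, so

    DLE (%) = c / 10,
    DEE (%) = DLE · (P + A) / A.

Efficiencies are kept unrounded internally; reports round half-up at two
decimals (`round_half_up`), the convention of printed lab tables (Python's
banker's rounding would turn 70.345 into 70.34).  Calibration lines are
forced through the origin (`a = slope · concentration`), with the slope
`Σxy/Σx²` and r² computed against the through-origin model; the assay
wavelength is carried only as metadata.

## Ritger–Peppas kinetics

`Mt/M∞ = k tⁿ` is fitted by ordinary least squares of `ln(Mt/M∞)` on
`ln t` — the linearized form in which such fits are conventionally plotted —
with a direct nonlinear mode as an option.  Choices:

* **Normalization.** Default `plateau` (M∞ = final observed release), with
  `total_load` (M∞ = 100 % of encapsulated drug) available; the exponent n
  is invariant to the choice, k is not.
* **Window.** Full curve by default; the classical "first 60 % of release"
  restriction is *not* applied automatically but can be imposed via
  `window`.  Points with `t ≤ 0` or `Mt ≤ 0` cannot enter the log–log
  regression; they are excluded and counted.
* n outside (0, 1) (e.g. a constant curve → n = 0) is flagged with a
  warning, not rejected: it is a diagnostic, not an invalid state.

## The multifractal Fokker–Planck release model

The states density of the drug coordinate obeys the relaxation–diffusion
(Ornstein–Uhlenbeck-type) equation

    ∂t ρ + ∂x(−η x ρ) − D ∂xx ρ = 0,

with diffusion-type coefficient D (units: release² / h), relaxation rate η
(1/h) and point initial condition at x₀.  Its transition density is a
Gaussian with mean `x₀ e^{−ηt}` and variance `σ²(t) = (D/η)(1 − e^{−2ηt})`,
saturating at D/η.  D carries the multifractal scale content through
`D = 2λ(dt)^{2/f(α)−1}`, where λ is the multifractal/non-multifractal
scale-transition coefficient, `dt` the scale resolution and f(α) the
singularity spectrum (f(α) = 2 — fractal dimension 2 — makes the exponent
vanish and λ = D/2 independent of resolution).

**Release law.**  The model is connected to a cumulative release curve by

    M(t) = σ(t) = √((D/η)(1 − e^{−2ηt})),

the only time-dependent scale of the transition density.  Its early-time
behaviour `√(2Dt)` has log–log slope 0.5, matching the Fickian exponent the
power-law fits find on the same curves, and its plateau `√(D/η)` matches
observed saturation.  This identification is a modelling choice of this
package: alternatives (e.g. first-passage release through an absorbing
boundary) would give different closed forms and are not implemented.  The
**fractalization degree** of a curve segment is *defined* as the fitted D,
with the amplitude degeneracy broken by fixing the prefactor of σ(t) to 1,
making (D, η) identifiable from (plateau, rate); the degrees are therefore
in generator units ((%)²/h) and are not unit-reconciled against any
externally tabulated values.

**Two-timescale fit.**  Curves are split at a breakpoint (default 50 h)
into an early and a late segment, fitted independently (no continuity
constraint — the segments represent dynamics at two different temporal
scale resolutions).  Each segment fit is a multi-start nonlinear least
squares in (log D, log η): η starts on a log grid spanning 10⁻⁴–10¹ 1/h, D
starts from plateau²·η.  The reported `early_mass_fraction` is
released(breakpoint)/released(end), linearly interpolated.

**Residuals.**  The default residual is the log-ratio of observed to model
release *increments* (the segment's first "increment" is its cumulative
level, anchoring the scale).  Rationale: each sampled aliquot of the
release assay contributes an independent proportional error, so increment
residuals are approximately i.i.d., while cumulative residuals are strongly
autocorrelated; with cumulative residuals the weakly identified η absorbs
noise curvature on segments deep in the √(2Dt) regime and inflates the
error of D several-fold.  `residual_mode="cumulative"` is available for
data whose error structure is genuinely on the cumulative values.  Reported
r² is always computed against the cumulative values.

**Verification oracles.**  Three independent routes check the closed form:
adaptive quadrature (unit mass and moments to 1e−8), a centered-difference
evaluation of the PDE operator on a uniform (x, t) mesh (pure
discretization error, second order: halving both spacings divides the
max-norm residual by ≈ 4), and a seeded Euler–Maruyama ensemble of
`dx = −ηx dτ + √(2D) dW`.  Euler–Maruyama has an O(step) variance bias
(the discrete stationary variance is `(D/η)/(1 − ηh/2)`), so ensemble
validation at 10⁵ particles uses step 0.002/η-scale rather than the 0.1/η
integration default; the stability bound step < 1/(2η) is enforced.

**Hydrodynamic diagnostics.**  From a positive density on a grid, with
amplitude `a = λ(dt)^{2/f(α)−1}`: the non-differentiable velocity
`V_F = a ∂x ln ρ`, the specific potential `Q = −2a² (∂xx √ρ)/√ρ`, and the
differentiable velocity `V_D = 2a ∂x s` for a supplied phase s (zero phase
→ V_D ≡ 0).  Derivatives are second-order centered differences; the
one-sided end stencils degrade the nested second derivative at the
boundary, so quantitative checks should be read on the grid interior.

## Cubic parameterization and SL(2,R) machinery

A nondegenerate real cubic `a₀X³ + 3a₁X² + 3a₂X + a₃` is parameterized by
the roots (h, h̄) of its Hessian covariant
`(a₀a₂−a₁²)X² + (a₀a₃−a₁a₂)X + (a₁a₃−a₂²)` and a parameter k via
`X_l = (h + ε^{l−1} h̄ k)/(1 + ε^{l−1} k)`, ε = (−1+i√3)/2.  Conventions:

* roots sorted by (Re, Im); h is the Hessian root with positive imaginary
  part (upper half-plane convention), or the larger root when the Hessian
  roots are real (the one-real-root cubic case);
* k is solved from X₁ (`k = (h−X₁)/(X₁−h̄)`), and the ε ↔ ε² branch is
  chosen by matching the two remaining roots; the max mismatch is stored as
  `reconstruction_residual`;
* degeneracy: |discriminant| < 1e−12·(coefficient scale)⁴ is an error, as
  is a₀ = 0 and the measure-zero family whose Hessian degenerates (leading
  coefficient a₀a₂−a₁² = 0, one Hessian root at infinity, e.g. X³ − 1).

For a cubic with three distinct real roots the Hessian roots are complex
conjugate and |k| = 1.  Homographies act on roots as
`X → (aX+b)/(cX+d)` and on the triple as h, h̄ → same homography,
`k → k(ch̄+d)/(ch+d)`; the two routes commute through the
parameterization (verified to ~1e−13 on random cubics).  The generators
`B₁ = ∂h + ∂h̄`, `B₂ = h∂h + h̄∂h̄`, `B₃ = h²∂h + h̄²∂h̄ + (h−h̄)k∂k`
satisfy `[B₁,B₂] = B₁`, `[B₂,B₃] = B₃`, `[B₃,B₁] = −2B₂`; brackets are
computed exactly (sympy polynomial vector fields) and the defect evaluated
at random points.

With `h = u + iv`, `k = e^{iθ}` the invariant metric is
`ds² = −(dθ + du/v)² + (du² + dv²)/v²`; imposing the angle-of-parallelism
constraint `dθ = −du/v` leaves the Poincaré half-plane metric
`(du² + dv²)/v²`.  In complex coordinates the equivalent form is
`(dk/k − (dh+dh̄)/(h−h̄))² − 4 dh dh̄/(h−h̄)²` — note the −4: `dh dh̄`
alone is `du² + dv²` while `(h−h̄)² = −4v²`, so the bare quotient
`dh dh̄/(h−h̄)²` differs from the half-plane metric by a factor −1/4.

## Harmonic pattern fields

The closed-form harmonic map
`h(Φ, α) = (cosh(Φ/2) − sinh(Φ/2)e^{−iα})/(cosh(Φ/2) + sinh(Φ/2)e^{−iα})`
solves the hyperbolic harmonic-map equation whenever Φ/2 is harmonic and α
is a real constant.  Its image has `Re h = 1/|cosh(Φ/2) + sinh(Φ/2)e^{−iα}|² > 0`
— the *right* half-plane model — so the conjugate field of the
Euler–Lagrange system is −conj(h), and the residual evaluated by
`euler_residual` is

    (h + h̄) ∇²h − 2 (∇h)²     (h̄ = complex conjugate),

equivalently: w = i·h solves the upper-half-plane equation
`(w − w̄)∇²w = 2(∇w)²` verbatim.  On an affine (harmonic) Φ the
centered-difference residual is pure discretization error and converges at
second order; a non-harmonic Φ (flagged) leaves an O(1) residual.

With `α = 2Ωt` the pattern field
`h(Ω,t) = i[e^{2Φ} sin 2Ωt − sin 2Ωt − 2i e^{Φ}] / [e^{2Φ}(cos 2Ωt + 1) − cos 2Ωt + 1]`
is evaluated on (Ω, t) grids (default 512², dimensionless axes — no unit
mapping to hours is asserted).  It is periodic in t with period π/Ω, equals
`e^{−Φ}` at t = 0 (so Im h ≡ 0 there), and has no poles: the denominator is
`(cos 2Ωt + 1)(e^{2Φ} − 1) + 2 ≥ 2` for Φ ≥ 0.  The Ω = 0 row is the
t-independent limit `e^{−Φ}`.  The reference parameter is Φ = 2.35
(`h(Ω,0) ≈ 0.09537`); h depends on (Φ, Ωt) only, which is the origin of the
fields' self-similarity across nested (Ω, t) ranges.  The two
implementations (the (Φ, α) form and the explicit (Ω, t) form) are
independent code paths kept in agreement to rounding.  Exported views:
|h| (global scale resolution), Re h (differentiable), Im h
(non-differentiable); the fields are qualitative pattern surfaces, not
quantitative release predictions.

## Synthetic panels

The generator stands in for measured release curves; its defaults are the
reference study conditions: samples A/B/C × pH 2/6.8/7.4, plateaus
95.2/94.3/94.1, 63.0/58.2/46.8, 80.8/61.6/58.8 % over 300/264/218-ish h,
power-law exponents 0.41–0.57 (`REFERENCE_PANEL`), 25 sampling points per
curve, denser before 50 h, no t = 0 row.  Generating laws:

* `ritger_peppas`: `released(t) = 100·k·tⁿ` capped at the plateau, with k
  derived so the plateau is reached exactly at the curve duration — the
  whole sampled curve is then a pure power law and (k, n) are recoverable.
  A pH-2 burst (plateau within hours) can be imposed via a per-curve k
  override; it is not the default because a full-window log–log fit of a
  burst curve cannot return the panel's reference exponents.
* `ou_release`: `M(t) = √((D/η)(1−e^{−2ηt}))` with η = D/plateau² (the
  configured plateau is the asymptote; whether it is *reached* within the
  duration depends on D).
* `two_regime`: early segment (≤ 50 h) and late segment (> 50 h) with
  distinct degrees D_early < D_late.  The late η is plateau-matched
  (η = D_late/plateau²); the early η is solved (Brent) so the release at
  the breakpoint is 30 % of the release actually reached at the end of the
  experiment.  When the early degree cannot reach that target (the
  breakpoint release is bounded by √(2·D_early·50)), the early η falls
  back to the late η; the recovered degrees are unaffected since segments
  are fitted independently.

**Noise model.**  Multiplicative Gaussian on release increments (relative
s.d. 2 % by default), then cumulated: curves stay non-decreasing and the
scatter is proportional to the step size, mimicking %-scale assay error.
All randomness derives from one mandatory root seed via
`numpy.random.SeedSequence.spawn`, so panels are byte-reproducible.

**What passing tests show.**  Recovery results on these panels demonstrate
estimator correctness and conditioning under the *assumed* error structure
(independent proportional increment errors, exactly model-true mean
curves).  Real release data add model misspecification, correlated
drift (temperature, evaporation, sampling-volume compensation) and
non-monotone raw readings, none of which the generator emulates; recovery
tolerances here are therefore lower bounds on real-data uncertainty.

## Problem sizes and determinism

Default verification sizes: 10⁵ particles for ensemble validation, 1000
random cubics for the geometry fuzz suite, 512² pattern grids, 201–401
point meshes for the PDE residuals; all chosen so the full suite and the
reproduction script run in well under a minute each on one CPU.  Every
stochastic path takes an explicit seed; recovery-under-noise statements
are evaluated as median errors over seeded replicate curves, since a
single draw measures the noise realization as much as the estimator.

## Known limitations

* The release law M(t) = σ(t) is one defensible mapping from the
  transition density to a cumulative curve; degrees fitted under a
  different mapping are not comparable.
* The breakpoint is fixed (default 50 h), not estimated; no continuity or
  changepoint inference across segments.
* The geometry module rejects Hessian-degenerate cubics rather than
  extending the parameterization projectively.
* `fit_ritger_peppas` requires strictly positive releases inside the
  window; heavy early censoring can leave fewer than 3 usable points.
* Efficiency arithmetic assumes the micelle powder mass is exactly
  polymer + drug (no residual solvent or salts).
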