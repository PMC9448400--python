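# micelkin

Release kinetics of drug-loaded polymeric nanomicelles.

`micelkin` is a Python toolbox for analysing cumulative drug-release curves
from pH-sensitive block-copolymer micelles (the motivating system is
curcumin released from poly(2-vinylpyridine)-b-poly(ethylene oxide)
nanomicelles at pH 2, 6.8 and 7.4).  It is aimed at formulation scientists
and modellers who need, in one place:

* **Loading arithmetic** — drug loading (DLE) and encapsulation (DEE)
  efficiencies from feed masses and assayed drug content, plus
  through-origin spectrophotometric calibration lines.
* **Classical kinetics** — the Ritger–Peppas power law
  `Mt/M∞ = k·tⁿ`, fitted by log–log least squares (n ≈ 0.5 signals Fickian
  diffusion).
* **A multifractal Fokker–Planck release model** — the states density obeys
  an Ornstein–Uhlenbeck-type equation
  `∂t ρ = ∂x(η x ρ) + D ∂xx ρ`, whose transition density is a Gaussian with
  mean `x₀ e^{−ηt}` and variance `(D/η)(1 − e^{−2ηt})`.  The cumulative
  release law is the standard-deviation growth
  `M(t) = √((D/η)(1 − e^{−2ηt}))`: `√(2Dt)` at early times (exponent 0.5),
  plateau `√(D/η)`.  Fitting it independently on an early (≤ 50 h) and a
  late (> 50 h) segment yields a per-timescale *fractalization degree*
  (the fitted D).  A seeded Euler–Maruyama particle ensemble serves as an
  independent stochastic oracle.
* **Hyperbolic geometry machinery** — the parameterization of nondegenerate
  cubics by their Hessian roots (h, h̄) and a unit-type parameter k, the
  induced SL(2,R) homographic action, its generators and bracket relations,
  and the reduction of the invariant metric to the Poincaré half-plane
  metric `(du² + dv²)/v²` under the angle-of-parallelism constraint
  `dθ = −du/v`.
* **Harmonic-map pattern fields** — the closed-form harmonic map
  `h(Φ, α) = (cosh(Φ/2) − sinh(Φ/2)e^{−iα}) / (cosh(Φ/2) + sinh(Φ/2)e^{−iα})`
  with `α = 2Ωt`, evaluated on (Ω, t) grids and exported at three scale
  resolutions (|h|, Re h, Im h) as pattern CSVs.
* **A synthetic-data generator** — seeded release-curve panels (3 samples ×
  3 pH values) with configurable plateaus, exponents, two-regime degrees
  and multiplicative increment noise, so every fitter in the pipeline is
  testable end-to-end without measured data.

## Worked example

```python
import micelkin as mk

# loading efficiencies for a 250 mg polymer + 25 mg drug feed
f = mk.Formulation(250.0, 25.0, 65.30, sample_id="A")
dle, dee = mk.compute_dle_dee(f)
print(f"DLE {dle:.2f} %  DEE {dee:.2f} %")

# a synthetic panel and its power-law exponents
panel = mk.generate_panel(mk.PanelConfig(seed=7, noise_rel=0.02))
c = panel[0]                       # sample A at pH 2
fit = mk.fit_ritger_peppas(c, normalization="total_load")
print(f"{c.sample_id} pH {c.pH}: n = {fit.n:.3f}, R^2 = {fit.r_squared:.4f}")

# two-timescale fractal fit of the same curve
r = mk.fit_multifractal_release(c, breakpoint_h=50.0)
print(f"degrees: early {r.D_early:.2f}, late {r.D_late:.2f}")
```

prints

```
DLE 6.53 %  DEE 71.83 %
A pH 2.0: n = 0.548, R^2 = 1.0000
degrees: early 13.96, late 16.78
```

DLE/DEE are percentages of the carrier+drug mass and of the drug fed; the
fitted exponent n ≈ 0.55 indicates a nearly Fickian release; the degrees
are the per-segment diffusion coefficients of the saturating release law in
(%)²/h — here the late degree exceeds the early one, the signature of a
release that keeps accelerating relative to a single saturating regime.

The same pipeline is available from the shell:

```bash
micelkin simulate-panel --seed 7 --out curves.csv
micelkin fit-rp      --curves curves.csv --out rp_report.csv
micelkin fit-fractal --curves curves.csv --out fractal_report.csv
micelkin patterns    --phi 2.35 --omega-max 20 --t-max 20 --view modulus --out pattern.csv
micelkin geometry-selftest
```

## Layout

```
src/micelkin/
  release_data.py          curve/report containers, CSV I/O
  loading_efficiency.py    DLE/DEE, calibration lines
  classical_kinetics.py    power-law prediction and fitting
  multifractal_kinetics.py OU density, PDE residual, hydrodynamics,
                           particle oracle, fractal fits
  sl2r_geometry.py         cubics, group action, brackets, metric
  harmonic_patterns.py     harmonic maps, pattern fields, Euler residual
  synthetic_data.py        seeded panel and formulation generators
  cli.py                   `micelkin` console entry point
docs/methods.md            model assumptions, estimator choices, limits
```
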