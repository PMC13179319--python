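# Methods

## The model

A sealed yeast fermentation chamber produces CO₂ that drives a piston pump.
Instantaneous pump rate over time t (minutes) is modelled as a product of
phase factors:

```
Q(t) = s_f · σ(s_t (t − t_i)) · D(t) · max(0, e − exp(t / t_e))
```

where `σ` is the logistic function. The three factors describe:

* **Startup** — `s_f σ(s_t (t − t_i))`: rehydration of the dry inoculum,
  metabolic adaptation (lag phase) and CO₂ saturation of the 1 mL medium are
  folded into one sigmoid with scale `s_f` (rate units), steepness `s_t`
  (1/min) and latency `t_i` (min). No mechanistic sub-models for these
  processes are attempted; their overlapping kinetics share the same
  sigmoidal shape.
* **Diauxic / stable** — `D(t) = 1 + σ(−(t − t_s)/t_ds)`, a multiplier in
  (1, 2) describing the transient dip ("wiggle") when the culture switches
  from glucose to fructose (both released by sucrose hydrolysis). The
  six-parameter model includes it; the four-parameter model sets it aside,
  trading instantaneous-rate fidelity for stability and better cumulative
  volume accuracy. Note the factor tends to 2, not 1, at early times; the
  form is implemented exactly as published.
* **Decline** — `max(0, e − exp(t/t_e))`: exponential shutdown of
  fermentation under substrate depletion, reaching exactly zero at the
  exhaustion time `t_e`, which is therefore the pump runtime. Cells stay
  viable; this is quiescence, not death.

Parameter invariants are enforced at construction: `s_f ≥ 0`, `s_t > 0`,
`t_i ≥ 0`, `t_e > t_i > 0`, and for the diauxic terms `t_ds > 0`,
`0 < t_s < t_e`. Phase factors accept any real t (they are mathematically
defined everywhere); the composite rate and volume evaluators reject t < 0
since model time starts at inoculation.

### Units

Published parameter sets carry `s_f` on a mL/min scale while pump rates are
quoted in μL/min. The package therefore attaches an explicit unit tag
(`"mL/min"` or `"uL/min"`) to every parameter set, trace and coefficient
table, and converts only through an explicit ×1000 (`to_unit`). Parameter
files must declare `rate_unit`; there is no default guess.

### Peak analytics

The time of maximum performance has the closed form
`t_max = t_i + ln(s_t t_e − 1)/s_t` (defined for `s_t t_e > 1`), and the
peak rate is the model evaluated there. This closed form is an analytic
approximation: the exact stationarity condition of the product differs
slightly, so `numeric_peak` locates the true argmax by a deterministic
grid-then-refine search (2048-point coarse grid, refined to 0.01 min). On
the two published parameter regimes the approximation lands within 5% of
the numeric argmax, and — because it evaluates the rate off-argmax — its
peak rate can never exceed the numeric maximum. Both are exposed; tests
assert both relationships.

### Cumulative volume

`V(t) = ∫₀ᵗ Q dτ` is computed by composite trapezoid on a fixed grid of
spacing ≤ 0.5 min clipped to `[0, t_e]`. The integrand is smooth and
bounded, so this deterministic, dependency-light rule agrees with a 0.05-min
oracle to well under 0.1% at `t_e`.

## Fitting

`PumpRateModel(trace, order=4|6).fit()` performs bounded nonlinear least
squares (SciPy trust-region reflective) on the rate residuals with all
parameters bounded below by zero, fixed starting values
`(s_f, s_t, t_i, t_e) = (0.005, 0.005, 100, 1000)` and a 400-evaluation cap.
For order 6 the extra starts are `t_s` = mid-span and `t_ds` = span/20.
Jacobian-based variable scaling (`x_scale='jac'`) lets the fixed start
converge on either rate scale; noiseless 3-min-sampled traces are recovered
to better than 10⁻⁶ relative. Volume traces are first differentiated
(`rate_from_volume`: centered differences, centered moving average of odd
width, default 3) because the fitting function is the rate expression.
Fits whose `s_f` is below 10⁻⁶ of the observed peak are flagged
`degenerate` rather than raised: an all-zero or pre-startup-truncated trace
has a flat optimum manifold and the optimizer may exit through any of it
(e.g. pushing `t_i` beyond the window); the flag, not the raw parameters,
is the signal.

Two metrics score a fit; both are invariant under joint unit rescaling:

* **rate NRMSE** = 100 · RMSE / (max − min) of the observed rates.
  Range normalization is a convention choice and is stated so the number is
  comparable across implementations; constant traces make it undefined.
* **volume error** = 100 · mean over sampled times of |V_model − V_obs| /
  V_obs(T). Normalizing the whole-run mean by the final volume penalizes
  drift accumulated anywhere in the run, which is the quantity a pump user
  cares about.

A six-parameter fit warm-started from a four-parameter solution
(`warm_start_from_four`: halve `s_f`, push `t_s` to just below `t_e`) can
only reduce the rate residual, giving a clean nested-model comparison.

## Configuration layer and inverse design

Each of the four parameters is an affine plane in the two dials a user
controls, yeast mass m (mg) and sucrose concentration s (wt%):
`p(m, s) = C_m m + C_s s + C_0`. The twelve coefficients of the published
syringe-pump calibration ship as `TABLE1` (s_f row on the mL/min scale).
Qualitatively: more yeast raises the peak rate and shortens the runtime;
more sucrose mostly extends the runtime. The planes are trusted on the
closed domain m, s ∈ [1, 5]; outside it evaluation warns
(`ExtrapolationWarning`) and design refuses. The published worked-example
parameter sets were read from the condition parameter chart, not from the
coefficient table — the two sources agree only approximately (the table at
(5, 3) gives t_e ≈ 921.5 vs the chart-read 1002.617) and are never mixed
silently.

`fit_coefficients` refits the planes from ≥ 3 calibrations by per-parameter
linear least squares; three non-collinear calibrations determine the planes
exactly, and collinear configurations raise a rank-deficiency error.
Tables are validated at construction: the derived `t_e(m,s) > t_i(m,s) > 0`
must hold at the four domain corners.

`inverse_design(target_Q_max, target_runtime)` mirrors the experimental
control strategy — choose yeast mass for the peak rate, then sucrose for the
runtime (the t_e plane is affine in s, so that step is closed form). A
single pass with a nominal mid-domain sucrose level recovers the target only
approximately, because the peak rate depends weakly on sucrose through all
four planes; the two stages are therefore iterated to a fixed point
(first pass exactly as the single-pass strategy; convergence typically in a
handful of iterations). The solve is deterministic, never returns a
configuration outside the domain, and an unreachable target raises with the
closest achievable design attached.

## Trace pipeline

Kymograph processing consumes the extracted piston-displacement series
(pixels vs minutes; sub-pixel positions allowed), multiplies by a
volumetric calibration (μL/pixel) to get cumulative volume, and computes
mean flow rates over arbitrary windows by interpolated difference
quotients. Image processing itself stays in external tooling.

The back-pressure calculator is the Hagen–Poiseuille relation
`Δp = 8 μ Q L / (π R⁴)` with all four inputs required explicitly in SI
units (a μL/min convenience constructor is provided). No default channel
geometry or viscosity is assumed, and the semicircular cross-section of a
real droplet channel is deliberately not modelled — the circular-radius
form is applied exactly.

## Synthetic data

The generators emulate the study's measurement process: rates sampled every
3 min (the imaging cadence) over `[0, t_e + 2 dt]`, six replicates per
condition, additive Gaussian rate noise with σ = 4% of the peak rate, and
per-replicate multiplicative lognormal parameter jitter with CV = 5%
(mean-one, applied to every parameter) to mimic biological batch effects.
Volume traces integrate the (noisy) rate and can be quantized to a pixel
step. Replicate i derives its generator from `seed + i`, so every output is
a pure function of (inputs, seed) and any replicate can be regenerated in
isolation.

The noise model is phenomenological: the published figures show only
min–max envelopes across replicates, so the Gaussian/lognormal magnitudes
are stand-ins chosen to produce envelopes of a similar visual width, and
both are overridable. Passing tests on synthetic data therefore demonstrate
correctness of the estimation machinery under a plausible noise model —
they do not certify the noise structure of real kymograph data, which may
include autocorrelated drift, temperature excursions and pixel-quantization
artifacts beyond the optional uniform quantum modelled here.

## Numerical choices and limitations

* Logistic terms are always evaluated through the numerically stable branch
  (`scipy.special.expit`); exponents of order 60 occur at realistic times.
  In double precision the logistic saturates to its bounds for arguments
  beyond ~37, so the mathematically open factor ranges attain their bounds
  numerically.
* The decline exponent is clipped at 1 (t ≥ t_e gives exactly zero), so
  times far beyond exhaustion cannot overflow.
* Problem sizes: fitting tests use 3-min sampling over full runs
  (≈ 300–600 samples); recovery suites use 20 seeded parameter draws per
  property and 20 seeds per noise level for the noise-monotonicity check.
* No confidence intervals are computed (none are published to compare
  against); the fit reports residual norm and the two percentage metrics.
* Temperature dependence, osmotic inhibition at high sucrose, and
  mechanistic substrate-tracking ODEs are out of scope by design; the model
  is phenomenological and valid for m ≤ 5 mg, s ≤ 5 wt% at 37 °C.
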