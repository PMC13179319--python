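# yeastpump

Fermentation-kinetics modelling for yeast-powered passive micropumps.

A sealed chamber of instant dry yeast in sucrose solution produces CO₂ that
drives a piston, pumping a few μL/min for many hours with no external power.
This package models, fits, and designs such pumps for microfluidics
practitioners: it turns kymograph-derived piston traces into calibrated
rate curves, estimates the kinetic parameters of the pump, and answers the
two questions a user actually has — *what peak rate and runtime will this
yeast mass and sucrose concentration give me?* and its inverse.

## The model

The CO₂ production (pump) rate is a product of three phase factors,

```
Q(t) = s_f · σ(s_t (t − t_i)) · [1 + σ(−(t − t_s)/t_ds)] · max(0, e − e^{t/t_e})
        startup sigmoid          diauxic multiplier          decline
```

with `σ` the logistic function and t in minutes. `s_f` scales the peak
rate, `s_t` the startup steepness, `t_i` the startup latency, and `t_e` the
exhaustion time — which equals the pump runtime, since the rate is
identically zero beyond it. The diauxic multiplier captures the transient
dip when the culture shifts from glucose to fructose; dropping it gives the
simpler and more stable **four-parameter model**
(`s_f, s_t, t_i, t_e`). Peak performance has the closed form

```
t_max = t_i + ln(s_t t_e − 1) / s_t,     Q_max = Q(t_max)
```

and each parameter is, within the calibrated range m, s ∈ [1, 5]
(mg, wt%), an affine function of yeast mass m and sucrose concentration s —
the **two-parameter layer** that maps a pump configuration directly to
predicted performance.

## Worked example

The standard condition (5 mg yeast, 5 wt% sucrose) has fitted parameters
`s_f = 0.007291` (mL/min scale), `s_t = 0.026052`, `t_i = 159.6`,
`t_e = 1599.6`:

```python
>>> import yeastpump as yp
>>> base = yp.FourParams(0.007291, 0.026052, 159.6, 1599.6, "mL/min")
>>> yp.peak_time(base)
301.8370279812192
>>> yp.peak_rate(base.to_unit("uL/min"))
10.749555805027486
```

The pump peaks at t_max ≈ 301.84 min after inoculation at
Q_max ≈ 10.75 μL/min, then declines until the runtime t_e = 1599.6 min
(about 27 h). Fitting a synthetic noisy trace (3-min sampling, 4% rate
noise) recovers the parameters:

```python
>>> tr = yp.generate_trace(base, noise=yp.NoiseSpec(rate_sigma_frac=0.04, seed=7))
>>> print(yp.PumpRateModel(tr, order=4).fit().summary())
Yeast pump rate model (4-parameter)
============================================
   s_f      0.00726739  [mL/min]
   s_t       0.0270348  [1/min]
   t_i         159.761  [min]
   t_e         1592.33  [min]
--------------------------------------------
rate NRMSE            3.2380 %
volume error          0.1074 %
residual 2-norm   0.00922568
evaluations                9
converged               True
degenerate             False
```

The rate NRMSE (~3.2%) reflects the injected noise; the cumulative-volume
error (~0.1%) shows the four-parameter model tracks total pumped volume
closely. Forward prediction and inverse design through the packaged
calibration table:

```python
>>> yp.predict_performance(yp.PumpConfig(3, 3))
PerformanceEstimate(t_max=312.0272059675742, q_max=5.942638126826812, runtime=1422.41134)
>>> d = yp.inverse_design(8.0, 1200.0)   # target 8 uL/min for 1200 min
>>> d.config
PumpConfig(m=3.900037345984202, s=3.0099033489185087)
```

i.e. 3 mg yeast with 3 wt% sucrose should deliver ~5.9 μL/min for
~1422 min, and a pump targeted at 8 μL/min over 1200 min needs about
3.9 mg yeast at 3.0 wt% sucrose. A `yeastpump` console script exposes the
same operations (`predict`, `fit`, `predict-config`, `design`, `calibrate`,
`kymo`, `pressure`, `simulate`); try `yeastpump --help`.

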