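# pulsepop

Climate-driven consumer–resource dynamics for mast-seeding forests:
predicting invasive house-mouse (*Mus musculus*) outbreaks from summer
temperature.

## The problem

In New Zealand beech forest, mice irrupt after mast years — episodic,
synchronized heavy seedfall. Outbreaks cascade to stoats and native
fauna, so managers need advance warning. Seedfall itself is well
predicted by the *change* in mean summer temperature between the two
summers before seeding (ΔT<sub>y</sub> = T<sub>y−1</sub> −
T<sub>y−2</sub>), which makes a purely climate-driven forecast of
consumer outbreaks possible: temperature → seedfall → mouse dynamics.

`pulsepop` implements that chain as a tested pipeline for ecologists
working with annual seedfall records and quarterly trap-catch indices
(captures per 100 trap-nights, C/100TN):

* **Seedfall models** — OLS regressions log₁₀(F<sub>y</sub>) = a + b·x
  with x = T<sub>y−1</sub> (T model) or x = ΔT<sub>y</sub> (ΔT model);
  mast-year classification by standardized deviates; climate thresholds
  (T<sub>thres</sub>, ΔT<sub>thres</sub>); mast-frequency statistics;
  mean/variance bias adjustment of climate-scenario series.
* **Consumer–resource ODE** — mouse abundance M and seed availability F:

      dM/dt = (α·g(F) − μ₁ − μ₂M)·M
      dF/dt = S(t) − hF − g(F)·M

  with the annual seed crop F<sub>y</sub> delivered at a constant rate
  over the February–April quarter, F reset to zero each February, and
  four functional responses g(F): Holling I (piecewise linear), Ivlev,
  Holling II, and uncapped. Integration is fixed-step RK4 run quarter by
  quarter (compiled with numba) so the pulse discontinuities fall on
  segment boundaries.
* **Fitting** — RMSE minimization against quarterly observations by
  bounded multi-start Nelder–Mead; AICc model comparison; nonparametric
  (case-resampling) bootstrap confidence intervals.
* **Outbreak thresholds** — long-horizon (default 1000-year) simulation;
  annual spring (August) peak and February→August finite rate of
  increase regressed against ΔT and log₁₀ seedfall with logistic vs
  linear fits; a large AICc advantage for the logistic curve is the
  signature of an outbreak threshold. The practical rule of thumb this
  supports: ΔT < 0 °C — outbreak unlikely; ΔT > 1 °C — outbreak year
  almost guaranteed.
* **Synthetic data** — seeded generators for temperature, seedfall, and
  observed-abundance fixtures with the field data's structure (43-year annual
  record, 100 quarterly observations), so the whole pipeline is testable
  without field data.

## Worked example

```python
import pulsepop as pp
from pulsepop.fitting import FitConfig

# synthetic study-shaped data: 43-year seedfall record, 25 years of
# quarterly abundance with 10% observation noise
temps, seedfall, quarterly = pp.make_fixture(pp.FixtureConfig(seed=0))

reg = pp.fit_seedfall_regression(temps, seedfall, mode="dT")
print(f"log10(F+1) = {reg.intercept:.2f} + {reg.slope:.2f} dT, r^2 = {reg.r_squared:.2f}")

masts = pp.classify_masts(seedfall)
stats = pp.mast_interval_stats(masts.flags)
print(f"{masts.flags.sum()} mast years; proportion {stats.prop_single:.2f}")

fit = pp.fit_consumer_model(quarterly, seedfall, "ivlev", "simplified",
                            FitConfig(n_starts=8, seed=42))
print({n: round(float(v), 2) for n, v in zip(fit.param_names, fit.theta)},
      f"rmse={fit.rmse:.2f} r={fit.pearson_r:.2f}")
```

prints

```
log10(F+1) = 0.53 + 0.57 dT, r^2 = 0.61
10 mast years; proportion 0.23
{'c': 6.82, 'shape': 1.08, 'mu1': -1.05, 'mu2': 0.68, 'h': 10.71} rmse=0.33 r=0.99
```

The regression recovers a strong positive ΔT cue; roughly one year in
four is a mast under the generator's settings; and the fitted Ivlev
parameters land near the generating values (c₂ = 6.74, e = 1.08,
μ₁ = −1.23, μ₂ = 0.76, h = 9.48) despite the observation noise. The
food-free equilibrium −μ₁/μ₂ ≈ 1.6 C/100TN is the baseline abundance
between masts, and exp(−h/2) < 0.05 means the seed bank empties within
six months of a pulse.

The same operations are available from the shell:
`pulsepop fixture`, `pulsepop validate`, `pulsepop seedfall fit`,
`pulsepop masts classify`, `pulsepop simulate`, `pulsepop fit`,
`pulsepop scenarios adjust`, `pulsepop step4` (see `--help`).

## Layout

```
src/pulsepop/
  timeseries_io.py     annual & quarterly containers, CSV I/O, dT
  seedfall_model.py    regressions, mast classification, thresholds, scenarios
  consumer_model.py    the pulsed consumer-resource ODE (numba RK4 core)
  fitting.py           RMSE fitting, bootstrap CIs, AICc comparison
  outbreak_analysis.py spring peak / winter increase, logistic thresholds
  synthetic_data.py    seeded generators and fixture writer
  cli.py               click entry points
docs/methods.md        model, assumptions, numerical choices, limitations
```
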