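# Methods

## Model

The package couples a climate-driven resource model to a mechanistic
consumer model.

**Resource (seedfall).** Annual beech seedfall F_y (seeds m⁻²) is
modelled on a log scale as a linear function of a temperature cue:
either the previous mean summer temperature T_{y−1} (T model) or the
two-summer change ΔT_y = T_{y−1} − T_{y−2} (ΔT model). Because observed
records contain near-zero years, an additive offset (default 1 seed m⁻²)
is applied before the log₁₀ transform and subtracted after
back-transforming, with predictions floored at 0. The offset is
configurable; the floor means the regression and generator are exact
inverses of each other only where a + b·x ≥ log₁₀(offset), and the
inverse tests are run in that regime.

**Consumer (mice).** Abundance M (C/100TN index) and available seed F
evolve as

    dM/dt = (α·g(F) − μ₁ − μ₂M)·M
    dF/dt = S(t) − hF − [g(F)·M]

S(t) delivers the annual crop F_y at constant rate F_y/0.25 over the
first quarter of a February-start annual cycle and is zero otherwise;
F resets to 0 each February (no seed carry-over). g(F) is one of four
functional responses (Holling I piecewise, Ivlev, Holling II, uncapped).
μ₁ is stored with its fitted sign — the growth term is −μ₁, so negative
fitted μ₁ means positive density-independent growth — and −μ₁/μ₂ is the
food-free equilibrium abundance. Two structures are exposed: the *full*
structure (α free, consumption feedback g(F)M in the resource equation)
and the *simplified* structure (α ≡ 1, no feedback), which is the one
that fits stably; the full structure is retained to demonstrate its
α–c ridge (see Fitting).

## Time conventions

All internal time is a real-valued year with February = offset 0;
quarters map to offsets {Feb: 0, May: 0.25, Aug: 0.5, Nov: 0.75}.
ΔT is indexed by the seedfall year it predicts. Annual series must be
gap-free (the resource driver cannot have holes); quarterly series may
be sparse and the objective simply skips missing quarters — the field
protocol could miss trapping sessions, and no imputation is attempted.

## Numerics

* **Integrator.** Classical fixed-step RK4, default dt = 1/400 year
  (100 steps per quarter), integrating each quarter as a separate
  segment so the pulse discontinuity and the year-start reset fall
  exactly on segment boundaries. Adaptive step control is avoided
  deliberately: discontinuous forcing defeats error controllers at the
  jumps. States are floored at 0 after each step (clips counted); the
  kernel is numba-compiled. Correctness is checked against closed
  forms: the logistic solution for M when F = 0 (1e−4), the linear
  pulse–decay solution for F without consumption feedback (1e−6 at
  quarter boundaries), exact seed conservation with h = 0 (1e−9), and a
  dt-halving convergence bound (1e−4 on quarterly extractions).
* **Quarterly extraction.** Model abundance is read at quarter-start
  nodes (Feb, May, Aug, Nov), matching how trap sessions align with the
  continuous model. The node at a year start records F after the reset.
* **RMSE objective.** Predictions at the observed (year, quarter) cells;
  simulation starts at the first observed year with M0 equal to the
  first observed February value. Bootstrap resampling enters as
  multiplicity weights.
* **Optimizer.** Bounded Nelder–Mead from seeded multi-starts
  (log-spaced for scale parameters c, shape, α; linear for μ₁, μ₂, h),
  default 20 starts, bounds c ∈ (0, 100], shape ∈ (0.01, 50],
  μ₁, μ₂ ∈ [−10, 10], h ∈ [0, 30], α ∈ (0, 100]; best of all starts.
  Failed simulations return a large penalty value.
* **AICc.** Computed from the RMSE as n·ln(RMSE²) + 2K +
  2K(K+1)/(n−K−1) with K = (free parameters) + 1 for the error
  variance. Only ΔAICc across models on identical data is meaningful;
  absolute values are never compared across datasets.
* **Bootstrap.** Case resampling of individual quarterly observations
  (year-block resampling available as configuration), 100 replicates by
  default, percentile (2.5, 97.5) intervals, fully deterministic per
  seed. Replicates refit warm-started from the point estimate; an
  optional seeded log-space jitter on the warm start lets replicates
  explore weakly identified ridges — used to demonstrate that the full
  structure's α spreads more across replicates (CV(α) > CV(μ₂)) while
  c collapses toward small values, the instability that motivates the
  simplified structure. More than 20% replicate failures is an error.
* **Logistic threshold fits.** 4-parameter logistic
  y = A + (B−A)/(1+exp(−s(x−x₀))) (both asymptotes free, since the
  response plateaus are nonzero), least squares with data-driven
  multi-starts (asymptotes at the response extremes, midpoints at
  predictor quartiles, a ladder of slope scales, seeded jitter); the
  exponent is clipped at ±500 for overflow safety, and fits are
  canonicalized to s > 0. Linear comparison uses K = 3, logistic K = 5.
  Responses are fitted on the raw scale (log-scale fitting would be a
  trivial extension but is not the default).

## Mast classification and thresholds

Standardized deviates AD_y = (F_y − mean F)/SD(F) use the sample SD
(n−1). The mast threshold is AD_thres = min_y |AD_y|, and a year is a
mast iff AD_y > AD_thres (strict: ties are not masts). Climate
thresholds are the minima over mast years of T_{y−1} (T_thres) and
ΔT_y (ΔT_thres). Interval statistics over a boolean flag vector:
prop_single = flagged/years; prop_double = years beginning two
consecutive flags, divided by the total years; mean_gap = mean
difference of successive flagged indices (1 = consecutive). The seed
half-life under loss rate h is ln2/h; the fitted h ≈ 9.2–9.8 yr⁻¹
empties the seed bank to under 5% within six months.

Climate-scenario series are bias-adjusted by the affine map matching the
scenario's mean and SD on the overlapping years to the reference
record's; the map is applied to the whole scenario and is idempotent.

## Synthetic data

The generator reproduces the structure the analysis assumes:
i.i.d. normal summer temperatures (no autocorrelation), seedfall
log-linear in ΔT with normal residuals on the log scale (floored at 0),
and quarterly observations equal to the model's own extractions times
unit-median lognormal noise (σ² = ln(1+CV²)), standing in for trap-catch
sampling and the saturation adjustment applied to raw field catches.
Defaults: 43-year annual record with two extra temperature years so
every seedfall year has its ΔT cue; 25 quarterly years = 100
observations; regression a = 0.33, b = 0.97 (the fitted ΔT model);
consumer parameters from the Ivlev observed-seedfall fit (c₂ = 6.74,
e = 1.08, μ₁ = −1.23, μ₂ = 0.76, h = 9.48); M0 = 1.0 C/100TN.
Temperature mean 16.4 °C and SD 0.7 °C and log-residual SD 0.45 are
synthetic choices producing a realistic mast regime (roughly one mast
year in four to five); they are not field estimates and should not be
cited as such. Files are written with 6-significant-digit formatting so
fixtures are byte-identical per seed.

What the generator does *not* emulate: within-year variation in breeding
onset, trap-level sampling detail and saturation nonlinearity, spatial
structure, predators, and any autocorrelation or trend in temperature.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the stated assumptions, not field realism.

## Problem sizes

Defaults follow the field sampling design: 100 quarterly observations for
fitting, 100 bootstrap replicates, 1000-year outbreak simulations. The
test suite uses the same shapes but economizes elsewhere — fewer
optimizer starts (4–8), 50-replicate bootstraps, dt = 1/100 in the
resampling-heavy checks, and a 300-year horizon where only determinism
or qualitative structure is asserted; the headline threshold analysis is
still exercised at the full 1000-year horizon.

## Known limitations

* The trap-saturation transformation applied to the original raw catch
  data is not modelled beyond the abstract observation-noise layer.
* The full structure's α is weakly identified by design of the test
  (the α–c ridge); its bootstrap intervals are exploratory, not
  inferential.
* The winter-increase response carries year-to-year carry-over of
  consumer density that the logistic curve cannot absorb, so its
  curve–point correlation is slightly lower (≈0.97) than the
  spring-peak pairings (≈0.995) on synthetic runs.
* Logistic threshold fits assume a single smooth threshold; multimodal
  or drifting regimes are out of scope, as are predator dynamics and
  spatially explicit prediction.
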