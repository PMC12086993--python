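# Methods

## Model

Per-plant aboveground dry biomass in a pot is treated as hyperbolically
density-dependent. With `N_self` and `N_other` the *realized* densities at
harvest (plants alive per pot, the focal plant included in its own species'
count), the mean model for a focal plant is

    w = wm * (1 + β*N_self + α*N_other)^(-b)

and its monoculture special case `w = wm * (1 + a*N)^(-b)`. `wm` (grams) is
the biomass intercept at zero density; `a`/`β`/`α` are per-plant crowding
coefficients (dimensionless per plant); `b` is the dimensionless decay
exponent, read in the yield-density literature as a resource-use-efficiency
parameter. Note the algebraic consequence that a *solitary* plant (`N = 1`)
has mean `wm * (1 + a)^(-b)`, not `wm`: the equations are followed literally,
with the plant counted in its own density, and the simulator and the fitters
share this convention.

Estimation is nonlinear least squares on the natural-log scale,
`ln w = ln wm - b*ln(1 + a*N)` and its biculture analogue, which is also the
noise model of the synthetic generator (multiplicative lognormal biomass
errors are additive Gaussian on `ln w`). The analysis is two-stage, following
the source methodology: the monoculture stage estimates `(wm, a, b)` per
species; the biculture stage then holds `b` fixed at the focal species'
monoculture estimate and estimates `(wm, β, α)`.

## Fitting and inference

* Internal parameterization: all free parameters are estimated as logs
  (`ln wm`, `ln a`, `ln b`; `ln wm`, `ln β`, `ln α`), which enforces
  positivity without constraint machinery. Internal parameters are
  box-bounded at ±30 (coefficients between e⁻³⁰ and e³⁰) purely to keep the
  optimizer finite on degenerate data.
* Optimizer: `scipy.optimize.least_squares` (trust-region reflective) with
  analytic Jacobians, `ftol = xtol = gtol = 1e-14`, at most 10,000 residual
  evaluations, and up to 10 jittered restarts on non-convergence. Starting
  values: `wm₀` = mean biomass at the lowest observed density, all other
  parameters 1.
* Covariance: residual-variance-scaled `(JᵀJ)⁻¹` at the optimum, computed
  through the SVD of `J` so that it stays positive semidefinite even when the
  fit is weakly identified. Natural-scale standard errors are delta-method
  (`SE(θ) = θ · SE(ln θ)`). Wald `t = estimate/SE` with a Student-t reference
  on `n - 3` degrees of freedom; two-sided p-values.
* Confidence intervals are computed on the log scale and back-transformed,
  `exp(ln θ̂ ± t₀.₉₇₅ · SE(ln θ̂))`, so they respect positivity and degrade to
  `(0, ∞)` when a parameter is unidentified.
* Pseudo-r² is `1 - SSE/SST` on the log scale (SST about the mean log
  response; undefined, returned as NaN, when SST = 0). No other definition is
  claimed; published pseudo-r² values computed under an unstated formula may
  differ.

### Identifiability

Two intrinsic ridges matter in practice and are deliberately *reported*
rather than papered over:

1. **Weak-crowding ridge.** When `a·N ≪ 1` over the design,
   `(1 + aN)^(-b) ≈ exp(-abN)` and only the product `a·b` is identified; the
   monoculture stage then returns extreme `(a, b)` pairs with correspondingly
   enormous standard errors.
2. **Strong-crowding ridge.** When densities make `β·N_self + α·N_other ≫ 1`,
   the transformation `(λβ, λα, wm·λᵇ)` leaves the fit almost unchanged, so
   `wm` and the absolute coefficient scale are weakly identified (the
   coefficient *ratio*, and hence RCA, remains stable — the worked example in
   the README shows this).

Either way the SVD covariance yields huge variances and the intervals
honestly approach `(0, ∞)`. A consequence of the two-stage design is that an
error in the first-stage `b̂` propagates into the biculture coefficients as a
bias the second-stage standard errors do not see; interval calibration is
therefore demonstrated for the biculture stage given the correct exponent,
and end-to-end two-stage intervals should be treated as approximate. The
threshold and RCA summaries inherit this caveat.

## Outlier screening

Biomass values outside the Tukey fences `Q1 - k·IQR`, `Q3 + k·IQR`
(default `k = 1.5`) are removed before fitting, with fences computed on raw
grams, pooled across densities within each species × {monoculture, biculture}
group (four groups, mirroring the standard accounting table). Quartiles use
linear interpolation between order statistics at positions `p·(n-1)`; the
convention is recorded in each `FilterReport` so counts can be
sensitivity-checked against other quantile definitions. Groups smaller than
4 rows pass through unfiltered. The screen targets measurement/recording
errors in noisy data; on noise-free data the pooled IQR collapses to the
spacing between density-level means and the screen would flag whole density
levels, so the pipeline accepts `filter_k = None` to disable it (used by the
exact-recovery tests).

## Derived quantities

* **Decline threshold**: `N* = ((1-f)^(-1/b) - 1)/c` solves
  `(1 + c·N)^(-b) = 1 - f` for one coefficient `c ∈ {β, α}` at a time, the
  other species' density held at zero. `c = 0` returns `inf`. The point
  estimate is this analytic plug-in at the estimates; an alternative
  bootstrap-median summary can be read off the same draws but is not the
  reported point. (Published threshold point estimates for the motivating
  system are not reproduced by any plug-in inversion of the published
  coefficients — the printed points sit near the geometric mean of the
  printed interval bounds — so the solver's correctness is established
  against a root-finding oracle and by interval calibration instead.)
* **Threshold intervals**: seeded parametric bootstrap. Parameter vectors
  are drawn from a multivariate normal on the internal log scale (every draw
  therefore has positive coefficients), centred at the estimates with the
  fitted covariance; each draw is inverted analytically and the 2.5%/97.5%
  percentiles reported. Default 10,000 draws. Draw exponents are clipped at
  ±700 so unidentified fits yield huge finite intervals rather than 0/inf.
* **RCA**: `β/α`, with `1/RCA` reported as the density equivalence (number
  of allospecific plants with the same per-capita effect as one
  conspecific).

## Synthetic experiment generator

The generator emulates the addition-series greenhouse design: monocultures
of each species at densities {1, 2, 4, 8, 16}, bicultures at all nine ordered
pairs from {2, 4, 8}, four replicates (76 pots). Plant survival from planting
to harvest is i.i.d. binomial per plant (default survival probability 0.9,
reflecting that dense pots rarely hold their planted counts to harvest);
biomass is the biculture mean model at the pot's realized densities times
`exp(ε)`, `ε ~ N(0, σ²)` per plant. Default parameter magnitudes are the
fitted values for the *B. tectorum* / *V. dubia* system
(`wm = 0.113/0.02808` g, `b = 0.96848/0.96730`, `β = 0.1309/0.5751`,
`α = 5.6387/1.8818`); the default noise `σ = 0.5` was calibrated once so that
log-scale fits land at pseudo-r² ≈ 0.2–0.6, the range observed for such data,
and left fixed.

What the generator does *not* emulate: density-dependent or clustered
mortality, germination-timing differences, spatial arrangement within pots,
belowground interactions, and any monoculture-specific crowding distinct from
`β` (the single-`β` world means simulated monocultures sit in the
weak-crowding regime for a species like *B. tectorum* whose `β` is small, so
simulated first-stage `b̂` is far noisier than the published monoculture fits,
whose crowding estimates were 9.18 and 222.14). Passing recovery tests on
synthetic data therefore demonstrates correctness of the estimators and
intervals under the stated generative model, not that a four-replicate
greenhouse design pins down every parameter of real data.

## Numerical conventions

Biomass is exported at 0.001 g resolution (floored at 0.001 g) while
in-memory values keep full precision; coefficient tables round to 4 decimal
places and threshold tables to 5, matching conventional reporting. All
randomness flows from explicit seeds; the pipeline splits one master seed
deterministically per stage, making whole-run outputs byte-reproducible.
Monoculture/biculture membership is decided by *planted* composition, so a
biculture pot in which one species died out entirely stays in the biculture
partition with a zero realized density.
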