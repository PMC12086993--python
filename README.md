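# addseries

Analysis of two-species **addition-series** competition experiments — the
greenhouse design in which two plant species are grown in monoculture along a
density gradient and in biculture at all density pairs, so that intraspecific
and interspecific density dependence can be separated. The motivating system
is the invasive annual grasses *Bromus tectorum* (cheatgrass, `BRTE`) and
*Ventenata dubia* (ventenata, `VEDU`), but the machinery is generic for any
two-species design of this shape.

## What it computes

Per-plant aboveground dry biomass `w` (grams) is modelled as a hyperbolic
function of realized density at harvest:

* monoculture: `w = wm * (1 + a*N)^(-b)`
* biculture:   `w = wm * (1 + β*N_self + α*N_other)^(-b)`

where `wm` is the biomass intercept (mean biomass of an uncrowded plant), `a`
the monoculture crowding coefficient, `b` the decay exponent (interpreted as
mean species-specific resource use efficiency), `β` the per-conspecific and
`α` the per-allospecific competition coefficient. Fitting is nonlinear least
squares on `ln w`; the biculture stage keeps `b` fixed at the focal species'
monoculture estimate. From the fits the package derives:

* **decline thresholds** — the neighbour density at which per-capita biomass
  drops by 50% or 75% relative to `wm`, `N* = ((1-f)^(-1/b) - 1)/c`, with
  seeded parametric-bootstrap percentile confidence intervals;
* **relative competitive ability** — `RCA = β/α`; RCA < 1 means plants of the
  other species suppress the focal species more than its own conspecifics do,
  and `1/RCA` is the number of allospecific plants equivalent to one
  conspecific.

Outlier screening (Tukey fences, `Q1 - 1.5*IQR` / `Q3 + 1.5*IQR`, pooled per
species × monoculture/biculture group) and a synthetic experiment generator
(addition-series design matrix, binomial plant mortality, multiplicative
lognormal biomass noise) round out the pipeline, so every stage can be tested
by parameter recovery without the original data.

The model fitters are scikit-learn style estimators
(`MonocultureYieldDensity`, `BicultureCompetition`, `TukeyOutlierFilter`)
and compose with sklearn tooling; `fit_monoculture` / `fit_biculture` are
thin functional wrappers used by the pipeline.

## Worked example

Simulate a full design (19 pot compositions × 4 replicates) at the default
fitted-parameter magnitudes with mild noise, fit everything, and write the
report tables:

```python
from addseries import RunConfig, run_pipeline, report_tables
from addseries.simulate import DEFAULT_PARAMS

params = {sp: {**vars(p), "sigma_log": 0.15} for sp, p in DEFAULT_PARAMS.items()}
bundle = run_pipeline(RunConfig(simulation={"params": params}, n_boot=2000, seed=1))
report_tables(bundle, "demo")
```

`demo/summary.txt` then reads:

```
BRTE monoculture: ln w = ln 0.09650 - 2.45060 * ln(1 + 0.02921 N)   [pseudo-r2 0.77, n=112]
VEDU monoculture: ln w = ln 0.02502 - 1.02342 * ln(1 + 0.44250 N)   [pseudo-r2 0.92, n=106]
BRTE biculture:  ln w = ln 0.02023 - 2.45060 * ln(1 + 0.00327 N_self + 0.16606 N_other)   [pseudo-r2 0.93, n=145]
VEDU biculture:  ln w = ln 0.03154 - 1.02342 * ln(1 + 0.62694 N_self + 1.75933 N_other)   [pseudo-r2 0.87, n=139]
RCA(BRTE) = 0.020; one conspecific is matched by 50.72 plants of the other species
RCA(VEDU) = 0.356; one conspecific is matched by 2.81 plants of the other species
```

The generating parameters were `β = 0.575`, `α = 1.882` for `VEDU` (recovered
as 0.627 and 1.759) and `RCA` truths of 0.023 (`BRTE`) and 0.306 (`VEDU`),
recovered as 0.020 and 0.356. Note the `BRTE` row illustrates a real feature
of this model family: when crowding is weak, `(a, b)` trade off along a ridge
(here `b` inflated to 2.45, shrinking both coefficients), yet RCA is nearly
unaffected because the shared exponent cancels in the ratio — see
`docs/methods.md`. `demo/thresholds.csv` gives the decline densities, e.g. a
50% decline of `VEDU` biomass from 0.55 (CI 0.28–1.04) `BRTE` neighbours.

The same run is available from a shell:

```bash
addseries simulate --seed 4 --out sim.csv
addseries filter --in sim.csv --out kept.csv --report table1.csv
addseries fit --in kept.csv --out fits.json
addseries thresholds --fit fits.json --nboot 10000 --seed 1 --out thresholds.csv
# or everything at once from a YAML config:
addseries run --config config.yaml --outdir results/
```

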