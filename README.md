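# thetagrow

Analysis of evolved population dynamics in replicated clonal growth
experiments: theta-logistic density dependence, nonlinear mixed-effects
estimation, and AICc model selection.

## The problem

Resurrection-ecology experiments compare *Daphnia* clones hatched from
decades-old resting eggs ("pre-invasion") with contemporary clones
("post-invasion") to ask whether a predator invasion drove evolution of the
prey's population dynamics. Each clone founds many single-individual
populations whose abundance (counts) and total dry biomass (mg) are
censused every ~8 days for ~3 months. `thetagrow` turns such census tables
into the three population-dynamics parameters of the theta-logistic model

    G = r (1 - (N/K)^θ)

where `G` is the daily per-capita growth rate at density `N`, `r` the
intrinsic growth rate, `K` the carrying capacity, and `θ` the shape of
density dependence — and tests whether `r`, `K` and `θ` differ between
invasion-history groups.

The analysis follows the two-stage design that defuses the r–θ likelihood
ridge:

1. **Observed r** per population from the founding abundance and the second
   census, `r = ln(N₂/N₀)/d`, analysed with a linear mixed model
   (invasion-history effect, clone random intercept) vs. its null.
2. **Theta-logistic NLME** on growth rates of all later census intervals,
   with observed r as a per-population offset, nested random effects of
   clone and population-within-clone on log K, and four candidates letting
   `K` and/or `θ` depend on invasion history (k = 7, 6, 6, 5 parameters).
   The marginal likelihood uses a per-clone Laplace approximation; ML fits
   are compared by AICc with Akaike weights, and the best model is
   re-estimated REML-style for reporting.

A synthetic-data module simulates the full experimental design (2 groups,
8 + 11 clones, 10 populations each, demographic stochasticity, early
extinctions, clone heterogeneity), so the entire pipeline is testable
without any external data. See `docs/methods.md` for model details and
assumptions.

## Worked example

```python
from thetagrow import AnalysisConfig, run_study

out = run_study(AnalysisConfig(seed=1, measures=("numerical",)))
print(out["numerical"]["theta_comparison"].table.round(3))
print(out["contrasts"]["numerical"]["K"])
```

On the default synthetic study (seed 1) this prints the AICc ranking of
the four theta-logistic candidates,

```
                             label  k      AICc  dAICc  weight
0  K ~ invasion history, theta ~ 1  6 -2223.861  0.000   0.359
1                  K and theta ~ 1  5 -2223.638  0.223   0.321
2  K ~ 1, theta ~ invasion history  6 -2222.302  1.559   0.165
3   K and theta ~ invasion history  7 -2222.170  1.690   0.154
```

— the carrying-capacity effect model ranks first (the generating truth has
a K difference and a common θ) — and the contrast from the best
effect-containing candidate:

```
{'model': 'K ~ invasion history, theta ~ 1', 'weight': 0.359,
 'intercept_post': 50.85, 'difference_pre': -8.47, 'percent_increase': 19.98}
```

i.e. post-invasion populations saturate ~20% higher than pre-invasion ones
in this realization (generated with K = 50.88 vs 39.99 individuals; the
weights are diffuse because the realistic simulation adds census noise the
model does not see). The same objects are written as report files when `out_dir` is set:
the AICc comparison (`table1_*.csv`), the best r-model and theta-logistic
parameter tables (`table2_*.json`, `table3_*.json`) and `contrasts.json`.

The command line mirrors the stages:

```bash
thetagrow run --out-dir results/ --seed 1
thetagrow simulate --config config.yaml --out census.csv
thetagrow rates --census census.csv --out growth.csv --intrinsic-out r.csv
thetagrow fit --growth growth.csv --rates r.csv --out fits.json
thetagrow select --fits fits.json --out table1.csv
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end analysis from scratch: it simulates
the default study with the given seed, runs both measures through the
growth-rate, mixed-model and model-selection stages, writes the
comparison and parameter-table reports under `results/pipeline/`, prints
the group contrasts,
and writes the JSON summary to `--out`.
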