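# cesdemog

Spatio-temporal variance decomposition of songbird demographic rates from
constant-effort ringing (CES) data.

## The problem

Conservation actions for widespread but declining bird populations can be
targeted in *space* (improve poor sites) or in *time* (intervene in poor
years), and the right choice depends on how a species' demographic rates vary.
A rate that differs consistently between sites invites local action; a rate
that fluctuates between years — especially when good and bad years coincide
across sites — calls for forecasting and widespread action.  CES mist-netting
schemes, which operate fixed nets for fixed durations at fixed sites every
breeding season, yield exactly the per-site, per-year capture data needed to
measure this.

`cesdemog` is a pipeline for ecologists working with such ringing data.  It
takes per-capture records (ring, species, site, year, visit, age class),
applies the CES inclusion rules, fits hierarchical Bayesian models of two
demographic rates, and decomposes their variation into interpretable
statistics compared across species.

## The model

Each rate θ (adult apparent survival φ, or productivity — the proportion of
juveniles among captures) is modelled per site *k* and year *t* on the logit
scale under two random-effect structures:

* **spatio-temporal structure (STS)** model:
  `logit(θ_kt) = µ + ε_t + η_k`, with year effects `ε_t ~ N(0, T²)` and site
  effects `η_k ~ N(0, K²)`.  The statistic **STS = K² / (T² + K²)** is the
  spatial share of the site-plus-year variance: above 0.5, the rate varies
  more between sites than between years.
* **synchrony (ICC)** model:
  `logit(θ_kt) = µ_k + ε_t + η_kt`, with a year effect shared by all sites
  (`ε_t ~ N(0, T²)`) and a site-specific annual residual (`η_kt ~ N(0, P²)`).
  The intraclass correlation **ICC = T² / (T² + P²)** is the synchronous share
  of annual variance: near 1, good and bad years coincide across sites.

Productivity uses a binomial likelihood for the juvenile count among all
captures; survival uses the Cormack–Jolly–Seber likelihood (m-array form,
conditioning on first capture) with a per-site recapture probability
`p ~ Uniform(0,1)`.  Both statistics are computed per posterior draw, never
from ratios of posterior means.  Across species, the two rates are compared by
subsampling 700 posterior draws of each statistic per species, differencing
(productivity − survival), and averaging across species per draw; the
difference is significant when the 2.5–97.5% interval of that distribution
excludes zero.  Finally each species-rate is placed in a quadrant of the
STS × ICC plane (split at 0.5/0.5): **i** spatial–asynchronous, **ii**
spatial–synchronous, **iii** annual–asynchronous, **iv** annual–synchronous.

Because multi-country CES deposits are not redistributable, the package ships
a first-class synthetic-data generator that simulates the full observation
process (open adult population, Poisson recruitment, Bernoulli survival and
detection, binomial juvenile composition) from known (K², T², P²), so every
stage can be validated against ground truth.  Models are fitted with the
package's own adaptive Metropolis-within-Gibbs sampler (vectorized over
conditionally independent blocks, with slice and interweaving updates for the
variance scales); convergence is gated on the split-chain R̂ diagnostic.

## Worked example

Two small synthetic studies — productivity-like variances (K²=0.30, T²=0.10,
P²=0.40: spatial, asynchronous) and survival-like variances (K²=0.12, T²=0.18,
P²=0.36: more annual, more synchronous) — with 4 species at 20 sites over
2004–2014:

```python
import dataclasses
from cesdemog import (
    MCMCConfig, SimulationConfig, simulate_dataset, apply_ces_filters,
    build_site_year_counts, build_capture_histories, fit_productivity,
    fit_survival, compute_sts, compute_icc, compare_rates, classify_quadrant,
    true_sts, true_icc,
)
from cesdemog.ces_io import qualifying_site_years
from cesdemog.simulate import PRODUCTIVITY_REGIME, SURVIVAL_REGIME

mcmc = MCMCConfig(chains=3, warmup=800, draws=700)
prod_cfg = SimulationConfig(n_species=4, n_sites=20, rng_seed=1, **PRODUCTIVITY_REGIME)
surv_cfg = SimulationConfig(n_species=4, n_sites=20, rng_seed=2, **SURVIVAL_REGIME)

prs, peff, _ = simulate_dataset(prod_cfg)
srs, seff, _ = simulate_dataset(surv_cfg)
counts = build_site_year_counts(apply_ces_filters(prs, peff))
hists = build_capture_histories(apply_ces_filters(srs, seff),
                                site_years=qualifying_site_years(seff))

prod_sts, prod_icc, surv_sts, surv_icc = {}, {}, {}, {}
for i, sp in enumerate(sorted(counts["species_code"].unique())):
    mc = dataclasses.replace(mcmc, rng_seed=10 + i)
    sub = counts[counts["species_code"] == sp]
    ch = [c for c in hists if c.species_code == sp]
    prod_sts[sp] = compute_sts(fit_productivity(sub, "STS", mc))
    prod_icc[sp] = compute_icc(fit_productivity(sub, "ICC", mc))
    surv_sts[sp] = compute_sts(fit_survival(ch, "STS", mc))
    surv_icc[sp] = compute_icc(fit_survival(ch, "ICC", mc))
```

Printing per-species posterior means, the survival quadrant, and the two
cross-species comparisons (`compare_rates(..., n_sub=700, rng_seed=0)`) gives:

```
true productivity STS=0.75 ICC=0.20; true survival STS=0.40 ICC=0.33
SP01: productivity STS=0.59 ICC=0.31 | survival STS=0.32 ICC=0.50 -> survival quadrant iii
SP02: productivity STS=0.81 ICC=0.07 | survival STS=0.60 ICC=0.18 -> survival quadrant i
SP03: productivity STS=0.56 ICC=0.38 | survival STS=0.27 ICC=0.44 -> survival quadrant iii
SP04: productivity STS=0.80 ICC=0.18 | survival STS=0.37 ICC=0.26 -> survival quadrant iii
STS mean difference (productivity - survival): +0.299 [+0.082, +0.488] (significant)
ICC mean difference (productivity - survival): -0.107 [-0.274, +0.067] (not significant)
```

Productivity is recovered as predominantly spatial (STS well above 0.5) and
asynchronous, survival as more annual; the across-species STS difference is
significantly positive.  With only 4 species the ICC difference (−0.11, true
gap −0.13) is not yet significant — the subsampled interval narrows as species
are added, and at 26 species (see below) the same contrast is decisively
negative.

The same analysis runs from the shell:

```sh
cesdemog run-all --config pipeline.yaml        # simulate -> filter -> fit -> decompose -> compare
cesdemog compare --config pipeline.yaml --figures
```

Stages write delimited tables plus a JSON manifest under the output directory,
and a rerun with an unchanged config reuses finished stages.

## Layout

- `cesdemog.ces_io` — record reading/validation, CES protocol filters, and the
  two model-ready structures (site-year counts, capture histories)
- `cesdemog.simulate` — synthetic-data generator with known variance structure
- `cesdemog.cjs` — exact CJS history probability and m-array likelihood
- `cesdemog.models` — hierarchical fits (binomial productivity, CJS survival)
  and the MCMC engine
- `cesdemog.decomposition`, `cesdemog.comparison` — STS/ICC per draw,
  cross-species subsampled differences, quadrant classification
- `cesdemog.pipeline`, `cesdemog.cli` — resumable orchestration and the
  `cesdemog` command

See `docs/methods.md` for modelling details, numerical choices and known
limitations.
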