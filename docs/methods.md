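# Methods

This note documents the models, the synthetic-data generator, the sampler, the
numerical choices, and what the test suite does and does not establish.

## Demographic rates and data structures

The unit of data is a capture record: one individually ringed bird of one
species, caught at one site on one numbered visit in one calendar year, aged
as adult or juvenile.  Two derived structures feed the models:

* **Site-year counts** — distinct adult and juvenile individuals per
  (species, site, year).  An individual recaptured within a season counts
  once; the first record fixes its age class.  Productivity is the proportion
  of juveniles among all captured individuals, a relative index of breeding
  output (it is monotone in juveniles-per-adult: a proportion of 0.5 equals
  one juvenile per adult).
* **Capture histories** — per species-site, one binary row per individual
  *first captured as an adult*, over the site's retained year vector.  Birds
  ringed as juveniles are excluded from histories even if recaptured later as
  adults, so the survival estimand is adult apparent survival (true survival
  confounded with permanent emigration, as always with single-site
  mark–recapture).  Individuals seen at two sites get independent histories;
  between-site movement is not modelled.

### CES inclusion filters

Following the constant-effort protocol, filtering proceeds in a fixed order:
(a) keep site-years with ≥ 8 visits, (b) keep sites with ≥ 5 qualifying
years, (c) keep species-site pairs with ≥ 25 distinct adults **and** ≥ 25
distinct juveniles over the retained years.  Order matters (a site's
qualifying-year count is evaluated after the visit rule) and is part of the
contract.  Effort is a separate required input table (site, year, n_visits):
a visited year with no captures leaves no record, so effort cannot be
inferred from captures, and a record whose site-year is absent from the
effort table is an error rather than a guess.  Qualifying years are
determined from effort alone, not from whether a given species was caught.
The 25/25 rule counts distinct individuals (not capture events); a bird aged
juvenile in one year and adult in a later year contributes to both tallies.
Records outside the configured study window (default 2004–2014 inclusive)
are rejected at read time.

## Hierarchical models

Both rates are modelled on the logit scale under two structures:

* **STS structure**: `logit(θ_kt) = µ + ε_t + η_k`, `ε_t ~ N(0, T²)`,
  `η_k ~ N(0, K²)`; the statistic STS = K²/(T²+K²).
* **ICC structure**: `logit(θ_kt) = µ_k + ε_t + η_kt`, `ε_t ~ N(0, T²)`,
  `η_kt ~ N(0, P²)`; the statistic ICC = T²/(T²+P²).

Likelihoods:

* **Productivity**: `J_kt ~ Binomial(A_kt + J_kt, θ_kt)` with J juvenile and
  A adult individuals captured.  Site-years with no captures contribute
  nothing (their binomial index is zero).
* **Survival**: Cormack–Jolly–Seber, conditioning on first capture.  Histories
  are aggregated per site into an m-array (released at occasion *i*, next
  recaptured at *j*, or never again); the likelihood is the standard product
  of multinomials with cell probabilities
  `ν_ij = (∏_{t=i..j-1} φ_kt) · p_k · (1-p_k)^(j-i-1)` and tail probability
  `χ_i = 1 − Σ_j ν_ij`.  The exact per-history probability (marginalizing the
  death time by the χ recursion) is exposed separately
  (`cjs.cjs_history_probability`) and the test suite verifies the two forms
  agree to 1e-10 and that all possible histories sum to probability one.
  Year effects index the T−1 between-year intervals.

Recapture probability is one `p_k ~ Uniform(0,1)` per site, constant over
years, on the argument that constant effort motivates constant detection;
year-varying p is not implemented.  Dead recoveries, transience and
trap-dependence corrections are likewise out of scope.

Priors: half-Normal(0, 1.5) on √T², √K², √P²; Normal(0, 1.5²) on µ and each
µ_k.  These are proper and weakly informative on the logit scale (a logit-sd
of 1.5 spans essentially the whole unit interval of rates) and are
config-overridable (`Priors`); the values used are recorded in each fit's
diagnostics.

### Sampler

No probabilistic-programming backend is required: the models' conditional
independence makes a blocked Metropolis-within-Gibbs scheme efficient and
fully vectorizable in numpy.

* Effect blocks that are conditionally independent given the rest (year
  columns and site rows in the binomial models; site rows in CJS; cell-level
  interactions) are updated with simultaneous elementwise random-walk
  proposals and elementwise accept/reject.  CJS year effects, which couple
  all sites, are updated as sequential scalars.
* Every proposal scale adapts by Robbins–Monro toward 0.44 acceptance during
  warmup only; the post-warmup kernel is fixed, so retained draws come from a
  valid Markov chain.
* Likelihood-invariant **translation moves** (shift µ up, shift an effect
  vector down by the same amount, accepted on the prior ratio alone) mix the
  weakly identified mean-vs-effect-average directions; the ICC models get
  row- and column-wise versions for µ_k/η and ε/η.
* Variance scales get two updates per sweep: a centred slice-sampling step
  given the effects, interleaved with a non-centred rescaling move (propose
  σ' on the log scale and scale the whole effect vector by σ'/σ, Jacobian
  included).  This interweaving avoids the funnel that traps purely centred
  samplers when a variance is near zero.

Defaults are 3 chains × (1000 warmup + 1000 retained) draws, guaranteeing the
≥ 700 retained draws the comparison stage subsamples.  Convergence is gated on
split-chain R̂ ≤ 1.1 (via arviz) for the monitored scalars (variances, mean
level, mean recapture rate); an unconverged fit is flagged and the
decomposition refuses it unless forced.  The posterior also records
`rate_mean`, the per-draw average of θ over cells — the identified "overall
rate" summary (µ alone is not identified against the effect averages).  The
binomial sampler was cross-checked against lme4's maximum-likelihood fit of
the same binomial site+year random-intercept model (agreement on µ and, up to
the expected posterior-mean/ML-mode skew with 11 year levels, on the variance
components); CJS fits recover simulator truth, including p.

Degenerate inputs: one year (either rate) and, for survival, fewer than three
years, no recaptures anywhere, or mixed species are errors.  The STS
productivity fit accepts a single site (the site variance is then
prior-dominated); the ICC structure needs at least two sites.  The survival
fitter requires all sites of a species to share one retained year vector;
filtering real multi-country data can produce ragged year vectors, which are
rejected with an explicit error rather than silently re-aligned — a known
limitation of this desk-scale implementation.

## Decomposition and comparison

STS and ICC are computed **per posterior draw** and then summarized; a ratio
of posterior-mean variances would be biased for a ratio's posterior mean.
Draws with a zero denominator are dropped and counted (0/0 carries no
information; mapping it to 0.5 would invent some).

The cross-species comparison subsamples `n_sub = 700` draws per species
without replacement, independently for each rate, pairs them by position, and
averages the (productivity − survival) differences across species per
position.  Two separately fitted models have no natural joint iteration
index, so positional pairing after independent subsampling is the only
reproducible convention; the subsample streams are keyed by (species, rate
label), which makes the operation exactly antisymmetric under swapping the
two rates, and when `n_sub` equals the full draw count the identity order is
used so the full-draw statistic is reproduced with no seed dependence.  A
species with fewer than `n_sub` draws is an error unless `auto_reduce` is
set, which lowers `n_sub` to the smallest available count (the
minimum-iterations rule).  Significance is the 2.5–97.5% interval of the
mean-difference distribution excluding zero; no multiplicity correction is
applied across the two statistics.

Quadrants are assigned from posterior means: i (STS > 0.5, ICC < 0.5),
ii (STS > 0.5, ICC ≥ 0.5), iii (STS ≤ 0.5, ICC < 0.5), iv (STS ≤ 0.5,
ICC ≥ 0.5).  Exact ties at 0.5 — never observed in practice — go to the
annual side for STS and the synchronous side for ICC, a fixed documented
convention.

## Synthetic-data generator

The generator mirrors the analysis models with all three effect terms at
once: `logit(θ_kt) = µ + ε_t + η_k + η_kt` per species and rate, with
variances (K², T², P²) shared by both rates within a dataset and independent
realizations per species.  The observation process is an open adult
population: Poisson recruitment (default mean 25 new adults per site-year),
Bernoulli survival across each interval, Bernoulli detection
(`recapture_prob`, default 0.5) each year, capture events assigned uniformly
among visits (default 10 per season, satisfying the 8-visit rule).  Given A
captured adults, the juvenile capture count is drawn
`J ~ NegBin(A, 1 − ρ)` — inverse sampling of i.i.d. juvenile-vs-adult capture
events — which makes the binomial proportion-juvenile likelihood exact for
inference.  One root seed drives three substreams (effects, demography,
detection), so changing detection noise leaves latent rates untouched;
output is byte-identical across runs with one seed.

Default study conditions: 40 sites, years 2004–2014, mean survival
logit(0.5) and mean productivity logit ≈ 0.55 (typical for European
passerines at CES sites).  Two reference variance regimes are exported,
chosen to emulate the qualitative pattern reported for European songbirds —
productivity spatial and asynchronous, survival more annual and more
synchronous:

| regime | K² | T² | P² | STS | ICC |
|---|---|---|---|---|---|
| `PRODUCTIVITY_REGIME` | 0.30 | 0.10 | 0.40 | 0.75 | 0.20 |
| `SURVIVAL_REGIME` | 0.12 | 0.18 | 0.36 | 0.40 | 0.33 |

What the generator does **not** emulate: density dependence, transient
individuals, within-season timing, distance-decaying spatial correlation,
species-varying effort or variances, ring loss, and misaging.  Passing tests
on synthetic data therefore demonstrate correctness of the estimation
machinery under the stated generative model, not robustness to every
real-data pathology.

## Validation design

* **Exact oracles**: CJS probabilities against independent death-time
  enumeration and a sum-to-one partition over all histories of length ≤ 5 on
  a (φ, p) grid; the m-array likelihood against per-history products; STS/ICC
  per-draw values against brute-force recomputation (1e-12); CES filtering
  against an exhaustive reimplementation on 100 randomized fixtures.
* **Recovery**: at 40 sites × 11 years under the default productivity regime,
  the posterior-mean STS and ICC land within ±0.12 of the generative targets,
  averaged over a fixed five-seed replicate set (seeds 300–304) — eleven year
  effects make a single realization's variance noisy (relative sd ≈ 45%), and
  averaging replicates damps realization noise without touching the
  tolerance.
* **Calibration**: 95% credible intervals for each variance component cover
  the truth in ≥ 80% of 20 replicates, with each structure checked under its
  own generative counterpart: the STS model (which by design has no
  interaction term) on interaction-free data, the ICC model (exactly
  specified once µ_k absorbs site effects) under the full generator.  Under
  the full generator the STS model is deliberately misspecified — that is the
  point of fitting both structures — and its intervals then carry no coverage
  guarantee for the nominal components.
* **Directional contrast**: six species simulated per regime (with the
  regimes pushed apart: K²,T²,P² = 0.5, 0.05, 0.4 vs 0.05, 0.4, 0.15); the
  across-species STS difference must be significantly positive and the ICC
  difference significantly negative.

Problem sizes in the test suite (reduced chains of 2 × ~400–500 draws, 20–40
sites) were chosen so the full suite completes in a few minutes while keeping
every check's tolerance as stated above; `scripts/acceptance.py` uses 26
species × 20 sites with 2 chains × (500 + 500) draws.

## Pipeline

The five stages (simulate/ingest → filter → fit → decompose → compare) write
delimited outputs plus a JSON manifest recording the config hash, per-stage
input hashes, seeds, timings and per-fit convergence flags.  A stage whose
hash matches the previous run and whose outputs exist is skipped and its
outputs reloaded, so a failed or interrupted run resumes.  Per-fit MCMC seeds
are derived deterministically from the base seed and the (species, rate,
structure) labels, so adding a species does not shift the others' chains.  In
pipeline runs unconverged fits are recorded and carried forward by default
(`allow_unconverged`), since a multi-species run should not abort on one
flagged species; library users calling `compute_sts`/`compute_icc` directly
get the blocking behaviour unless they pass `force=True`.

## Known limitations

* Apparent survival confounds mortality with permanent emigration; nothing
  here separates them.
* Survival fits need a common year vector across a species' sites (see
  above).
* Recapture probability is site-constant; strong year-to-year effort changes
  within a site would be absorbed into φ.
* The six-model registry currently implements the two structures per rate
  that define STS and ICC; a third variant can be registered but none ships.
* The comparison treats species symmetrically; no phylogenetic or abundance
  weighting.
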