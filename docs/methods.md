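# Methods

`harvestcarbon` estimates the edible weight of wild-food harvests from a
monthly recall survey whose counts are *heaped* (clustered on round
numbers), and propagates the resulting posterior into three kinds of
accounting: the retail cost of market foods that would replace the harvest,
the greenhouse-gas emissions of producing and shipping those replacements
to remote Arctic communities, and the gasoline inputs (litres, dollars,
CO2e) of the harvesting itself. This note records the models, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions.

## 1. Deheaping measurement-error model

Recalled harvest counts cluster on multiples of 5, 10, and 50, with larger
counts more coarsely rounded. We treat each reported count $y_i$ as a
lognormal observation of a latent true harvest $t_i$:

$$\log y_i \sim \mathrm{Normal}(\log t_i,\ \sigma_{\mathrm{obs}}),
\qquad \sigma_{\mathrm{obs}} = 0.15 .$$

The observation scale is fixed, not estimated. The value 0.15 encodes the
empirical magnitude of heaping error via the median–SD relationship of the
lognormal: a report with median 10 has an SD of about 1.5 items
(`lognormal_sd(10, 0.15) = 1.53`), so reporting error grows in proportion
to the size of the estimate. Note the same identity gives an SD of ≈ 76
items at median 500, not 50: under a fixed log-scale SD the absolute error
is strictly proportional to the median, and we implement the formula
consistently rather than any rounder figure.

Each latent log harvest gets a species-type prior

$$\log t_i \sim \mathrm{Normal}(\hat\mu_{g(i)},\ \hat s_{g(i)}),$$

where $g(i)$ is the report's species type — a group of ecologically similar
species harvested by similar techniques (all geese pooled, all caribou
pooled, …) — and $(\hat\mu_g, \hat s_g)$ are the plug-in empirical mean and
sample SD (ddof = 1) of the logged non-missing reported counts in that
group. This is deliberately *not* a hierarchical hyperprior: the moments
are computed once from the observed data and held fixed, which makes the
posterior factorize over reports and keeps the model's behaviour
transparent. Groups with a single report or zero variance get a floor
$\hat s_g = 0.5$ (log scale), weakly informative enough not to pin the
latent. The shrinkage this prior induces treats very large reported
harvests with skepticism; it is a conservative choice that biases totals
slightly downward (see §6).

Flagged-missing reports (data-entry errors where an ID was recorded as a
count) carry no likelihood term; their latents are draws from the
species-type prior, i.e. imputation happens inside the same MCMC run
rather than as a post-hoc step. A `no_pooling` mode drops the species-type
prior for observed reports (flat prior on the log latent, so the posterior
is centred on the report itself with SD $\sigma_{\mathrm{obs}}$) while
keeping it for imputation; this isolates how much the pooled prior moves
the totals.

Latent harvests are continuous positive reals. Deheaping therefore yields
fractional counts; nothing downstream rounds them, and the fractional part
absorbs some real variability in animal size and usable portion.

## 2. Trip model

A separate dataset of monitored harvesting trips (132 trips with fuel
litres, edible kilograms, transport mode, and party size) identifies three
things the recall survey cannot: how often trips fail, how fuel scales
with harvest size, and how much fuel failed trips burn.

* Success: each trip succeeds with probability $\theta$,
  prior $\mathrm{Beta}(1,1)$.
* Successful trips: $\log \mathrm{fuel} = a + b \log \mathrm{kg} +
  \varepsilon$, $\varepsilon \sim \mathrm{Normal}(0, \sigma_r)$ — a power
  law on the natural scale. Priors: $a, b \sim \mathrm{Normal}(0,1)$,
  $\sigma_r \sim \mathrm{HalfNormal}(1)$. The covariate is centred
  internally to decorrelate intercept and slope; draws are transformed
  back.
* Failed trips: $\log \mathrm{fuel} \sim \mathrm{Normal}(\mu_f, \sigma_f)$
  with $\mu_f \sim \mathrm{Normal}(0,5)$ (realistic failed-trip fuel means
  sit near $\log 50 \approx 3.9$, which a unit-scale prior would shrink
  materially at the 30-odd failed trips available) and
  $\sigma_f \sim \mathrm{HalfNormal}(1)$.

Group-reported harvests are first normalized by `divide_group_harvests`:
snowmobile/ATV trips divide the harvest by the party size (expenses were
reported individually, so this is equivalent to assuming one machine per
participant), while boat trips keep the whole harvest (one boat per
party). Records with nonpositive fuel are excluded from the fuel blocks
(logged), but still count toward $\theta$.

Unobserved failures: treating each of the $n$ survey reports as one
successful trip, the number of failed trips accompanying them is
$\mathrm{NegBinom}(n, \theta)$ with mean $n(1-\theta)/\theta$; each failed
trip burns an independent lognormal $(\mu_f, \sigma_f)$ fuel draw. The
one-report-one-trip convention ignores multi-species and multi-animal
trips and therefore biases fuel (and the failure count) high; we keep it
because trip structure is unrecoverable from the survey.

## 3. Valuation and replacement emissions

Per posterior draw and report: kilograms = latent count × the species'
edible weight (per species, not pooled by type); value = kg × the
community's price for the replacement category (poultry, fish mix,
beef/pork mix) × a CPI adjustment (default 0.989, aligning a 2014–2016
price survey with the 2018 study year); emissions = kg ×
[production factor + Σ legs (distance × per-mode transport factor)].

Four transport scenarios share one config: road-south-then-barge and
road-then-air ("food mail") routes, each at low and high published
per-kg-per-km endpoints. Category blends (poultry as an even chicken
leg/breast mix; fish as 70% whitefish / 30% salmonid; mammal as 50/50
beef–pork) are folded into the per-category config numbers, not code.
Prices, edible weights, and emission factors carry no error model — the
scenario endpoints are the uncertainty statement for transport, and
production factors enter as point values. Aggregation is per draw by taxon
class (bird/fish/mammal) and total, so class totals are exactly additive
in every draw.

Gasoline accounting mirrors this: litres come from pushing each report's
kg draws through that same draw's regression parameters (alignment by draw
index is load-bearing and tested), plus simulated failed-trip fuel; cost
is litres × price (default $1.76/L, 2018); emissions are litres ×
[2.319 kg CO2e/L combustion + 0.749 kg/L density × shipping route
intensity], with shipping at low/high endpoints. Only direct emissions are
counted — no vehicle manufacture, no equipment embodied carbon.

## 4. Inference machinery

Both models are fitted by adaptive random-walk Metropolis, written in
`harvestcarbon.mcmc`: a joint sampler for the small trip-model blocks and
an elementwise sampler for the per-report latents (the deheap posterior
factorizes, so per-latent accept/reject is exact). Step sizes adapt only
during warmup (first half of iterations, Robbins–Monro toward 0.44/0.30
acceptance); kept draws form a valid chain. Defaults: 3 chains × 6,000
iterations for the deheap model and × 4,000 for the trip model — random
walks need more steps than gradient-based samplers to reach the same
effective sample size, and these defaults put the max split-R̂ across all
latents comfortably under the 1.01 reporting threshold. Convergence is
diagnosed by split-R̂ (own implementation, cross-checked against ArviZ's
ESS machinery); a fit exceeding the threshold is returned *flagged* with a
warning, never silently.

Working draws are thinned to a configured size (default 100 per estimand)
for downstream propagation; full-chain summaries (per-latent posterior
mean/SD and ESS) are kept at full precision for diagnostics and oracle
comparisons.

Because the deheap posterior is conjugate given the plug-in moments, the
normal–normal closed form (`conjugate_log_posterior`) is an exact oracle;
the test suite requires the MCMC to match it case by case within
Monte-Carlo error, which is a stronger check than any convergence
statistic.

### HPDI convention

`hpdi` returns the shortest window over the sorted draws spanning
$\lfloor 0.9 n \rfloor$ inter-point gaps ($\lfloor 0.9 n \rfloor + 1$
points), ties broken at the lowest start — the same convention as ArviZ,
verified against it and against exhaustive window search. For
$n$ not divisible the interval contains slightly *more* than the nominal
mass, never less.

## 5. Synthetic-data generator

The real survey and trip datasets are access-restricted, so the generator
is first-class code that emulates their statistical structure with known
ground truth:

* True counts lognormal per species type, with per-type log means/SDs
  spanning single large mammals (caribou log-mean 0.6) to batch harvests
  (whitefish/geese log-means 2.0–2.3, log-SD ≈ 1). With the default
  species mix and 2,388 reports this yields ≈ 120 t of edible weight —
  the scale the method is meant for.
* Heaping by a graded deterministic rule: exact below 5 (nearest integer,
  min 1); nearest 5 below 100; nearest 10 below 250; nearest 50 above.
  The real mechanism is unobserved; whether it is symmetric rounding or
  truncation is unknowable from the data, so the rule is exposed as a
  parameter (`HeapRule`) and every dataset carries its truth so no claim
  rests on the rule being real. Under the defaults the realized heaping
  error has log-scale SD ≈ 0.20, with the min-1 floor adding a small
  upward bias to reported totals (≈ +0.8% by weight).
* Missingness completely at random: exactly `round(missing_frac · n)`
  reports blanked and flagged (default 64 of 2,388). The real mechanism
  (ID/field confusion) is plausibly unrelated to harvest size, which CAR
  captures.
* Trips: Bernoulli success (default θ = 0.75), successful-trip kg
  lognormal (log-mean 3.0, log-SD 0.9), fuel from the power law
  (intercept 2.0, slope 0.5, residual SD 0.5), failed-trip fuel lognormal
  (3.8, 0.5). These defaults give ≈ 50 L per ≈ 50 kg trip and ≈ 52 L per
  failed trip — roughly 1–1.4 L of gasoline per edible kilogram at survey
  scale, the regime of interest.

What the generator does **not** emulate: month-by-month interviewer
availability and participation patterns, per-community failure rates,
multi-species trips, digit-preference idiosyncrasies beyond the graded
rule, and any dependence of missingness on harvest size. Passing
calibration tests therefore demonstrate internal consistency of the
method under its stated assumptions, not field validity.

## 6. Known limitations

* **Conservative totals.** The species-type prior shrinks large reports
  toward the group mean. On synthetic data this makes the posterior mean
  of total edible weight sit ≈ 1% below truth while the posterior SD of
  the total is ≈ 0.5%, so 90% intervals for the *total* cover truth below
  nominal rate (observed ≈ 76% over 50 replicate datasets; misses are
  almost all on the high side, concentrated in datasets containing several
  very large heaped reports). Per-report inference is well calibrated —
  it is the sum over thousands of slightly-shrunk latents that
  concentrates the bias. Users who need unbiased totals at the expense of
  robustness to overstated reports can use `no_pooling` mode.
* **Fixed σ_obs.** The observation scale 0.15 is a calibration constant,
  not an estimate; if true heaping noise is larger (the generator's
  realized 0.20, for instance) intervals are modestly anticonservative.
  It is exposed in `DeheapConfig` for sensitivity analysis.
* **One trip per report.** Fuel estimates are upper-bound-flavoured, as
  discussed in §2.
* **Config realism.** Shipped route distances, emission factors, and
  prices are illustrative defaults on the scale of the published
  literature, meant for synthetic studies; a real analysis replaces them
  with sourced values in `config.yaml`.

## 7. Problem sizes used in the test suite

Statistical tests run at the scales the method targets: survey-scale
deheap fits use 2,388 reports with 3 chains × 2,000–6,000 iterations;
the calibration and recovery harnesses use 50 replicate datasets each;
oracle-equivalence uses 100 single-report cases. The full suite completes
in a few minutes on one CPU.
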