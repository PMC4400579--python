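# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Pipeline overview

The surveillance statistic is a chain: a *filter* maps a message corpus to
a matched-id set; *rate normalization* maps the matched set to one number
per city, `rate_c = matched_c / total_c`; *validation* is the Pearson
correlation of `{rate_c}` against a per-city pollution measure (average or
maximum daily PM2.5, µg/m³). The filter layer is an exact boolean algebra
over three primitives — keyword match (exact token equality after
segmentation), topic match (via a fitted LDA state), and URL presence —
with AND/OR/NOT evaluated as set intersection/union/complement over the
corpus id set. Every `FilterResult` carries provenance (serialized
expression plus model fingerprints) sufficient to re-derive the identical
set.

## Topic model

LDA with symmetric Dirichlet priors, estimated by collapsed Gibbs sampling:
one sweep resamples every token assignment z_i from

P(z_i = k | z_-i, w) ∝ (n_dk + α)(n_kw + β)/(n_k + Vβ),

counts excluding position i. Point estimates are the smoothed ratios
θ[d,k] = (n_dk + α)/(len_d + Kα) and φ[k,w] = (n_kw + β)/(n_k + Vβ); an
empty document's θ row is the uniform prior.

Parameters and defaults:

* **K** (topics): 100 by default, matching the scale used for large health
  corpora; small K (≈10) suffices on synthetic corpora with few planted
  topics.
* **α** = 50/K and **β** = 0.01: the common defaults for this sampler
  family; the source analyses do not pin them down, so both are explicit
  configuration and are logged with every fit.
* **Sweeps**: 1000 by default (the setting used at production scale);
  convergence on well-separated synthetic topics occurs within ~100–200.
* A single chain, no burn-in/thinning machinery: filtering reads
  "assigned by the sampler" literally and uses the final-iteration
  assignment state. Post-burn-in averaging of θ and φ is available
  (`sample_average_start`) but is not the default, because the token
  criterion is defined on one concrete assignment state.

Topic *selection* — deciding which fitted topic is "the air-quality topic"
— is inherently a human judgment (inspection of top words). The pipeline
exposes an explicit `topic` override and an automatic stand-in (the topic
with the largest φ mass on the designated keyword tokens) for unattended
runs.

Numerical notes: the sweep kernel is numba-compiled and sequential by
construction; its RNG is reseeded deterministically per sweep from
(run seed, sweep index), making trajectories bit-reproducible regardless of
process history. Count tables are int32 (safe for any corpus the package
targets) and are verified against a full recount in the test suite.
`top_words` breaks probability ties by ascending token index so summaries
are reproducible.

## Surveillance statistics

`pearson` wraps the standard product-moment coefficient with strict error
semantics: fewer than 3 pairs or a zero-variance vector raise typed errors
rather than propagating NaN. City joining is exact after whitespace
trimming plus an optional caller-supplied alias map — no fuzzy matching,
because silently mis-joining city names would corrupt the statistic; cities
missing from either table are excluded and itemized, never imputed as rate
zero.

ADV- and MDV-based coefficients share the rate vector, so their comparison
uses the Meng–Rosenthal–Rubin z test for overlapping dependent
correlations, with the ADV–MDV correlation over the shared cities as the
third input. The choice of this particular dependent-correlation test is a
documented package decision (several variants exist); its type-I error is
verified by simulation in the test suite.

## Annotation module

The code tree is: relevant → {firsthand → {behavior, concern},
request_action}. A child code is `na` exactly when its parent chain is not
all-'y'; the validator reports violations and never repairs them.

Agreement per code uses the 2×2 contingency table of the two coders'
y/n values; κ = (p_o − p_e)/(1 − p_e) with p_e from marginal products. The
default applicability convention counts a message into a code's n only
when the code is applicable under **both coders' own** parent codes — this
is what makes n shrink down the tree (all messages for the root code, fewer
for firsthand, fewer still for behavior/concern). An alternative
("either", treating one coder's structural `na` as 'n') is available. When
both coders are constant, p_e = 1 and κ is undefined; the error still
carries p_o.

Adjudication merges top-down: agreed cells pass through; a coder's `na`
under their own unsatisfied parent counts as *not coded*, so when the
parent resolves to 'y' the coder who did code the cell wins alone, and only
genuine y/n conflicts go to the third coder. The output always satisfies
the hierarchy.

Summaries report conditional proportions against the parent count
(relevant of total, firsthand of relevant, behavior/concern of firsthand,
action of relevant), as exact fractions plus one-decimal percentages; an
empty denominator yields an undefined proportion, not 0. Coding guidance
that cannot be enforced in software (e.g. a general discomfort is not a
health concern unless explicit) lives in the schema documentation.

## Cascade classifier

Stage 1 (relevance) trains on all labeled messages; stage 2 (firsthand)
trains only on the relevance-positive labeled subset and is evaluated at
prediction time only where stage 1 predicts positive — so no message can be
labeled firsthand yet irrelevant. Features are contiguous word n-grams of
orders 1–3 with binary presence weighting (counts optional) and a
configurable frequency floor; both stages are logistic regressions with L2
regularization at unit strength by default. With ~10² training examples
and 1–3-gram features the problem is underdetermined, so regularization is
required for a defined optimum; the strength is configuration.
Cross-validation uses stratified folds with a recorded seed; folds are
redrawn (logged) in the rare event a training split is single-class.
Metrics are computed for the positive class from pooled out-of-fold
confusion counts; per-fold averages are reported alongside because both
conventions are common.

## Synthetic-data generator

The generator defines the study conditions for every test:

* **Cities**: 74 by default. ADV ~ Uniform(25, 160) µg/m³ — a uniform
  marginal is the simplest choice exposing the full dynamic range — and
  MDV = ADV × Uniform(2.5, 6), reflecting the typical ratio of a yearly
  maximum to a yearly mean for daily PM2.5.
* **Per-city message totals**: lognormal with mean 5479 and
  σ = √(2·ln(5479/3079)) ≈ 1.07, calibrated so the mean/median ratio
  matches the heavy right-skew of per-city social-media volume; σ is a
  knob (0 gives constant totals, used by the fixed-size validation runs).
* **Relevance link**: π_c = clip(π₀ + b·ADV_c, 0, 1), default π₀ = 0 and
  b = 1.25×10⁻⁴ per µg/m³, spanning rates ≈0.003–0.02 over the default
  pollution range. Linear-with-clipping is the default because the
  infinite-sample rate/ADV correlation then has a closed form
  (`expected_correlation`, the Pearson correlation of the realized π with
  ADV — exactly 1 when no clipping binds); a logistic link matched in value
  and slope at the range midpoint is available.
* **Text**: planted topic–word distributions φ\* (Dirichlet rows,
  concentration 0.05 over a 500-token vocabulary). The four keyword tokens
  are designated air-quality vocabulary: the planted AQ topic carries them
  with a fixed 0.15 mass share and background topics give them none, so
  keyword occurrence in irrelevant messages is governed solely by
  `keyword_noise_prob` (0.01) and in relevant messages by organic AQ-topic
  draws plus injection with `keyword_injection_prob` (0.8). Relevant
  messages draw each token from the AQ topic with probability 0.7,
  otherwise uniformly from background topics; irrelevant messages use
  background topics only. Document lengths are 1 + Poisson(8).
* **Metadata**: URL flags at 0.15 (relevant) vs 0.35 (irrelevant),
  account types at the observed individual/government/company/media
  proportions (99.31/0.14/0.49/0.06%), and hierarchical content labels at
  the observed conditional proportions (firsthand|relevant 90/114,
  behavior|firsthand 32/90, concern|firsthand 17/90, action|relevant
  3/114).
* **Coders**: two annotators who independently flip each true label with
  probability 1 − accuracy, masked to the hierarchy under their own codes.
  For the root code this yields a closed-form expected κ (exposed as
  `expected_kappa`): p_o = a² + (1−a)² independent of prevalence, with p_e
  from the flipped marginals.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: natural language (tokens are abstract
symbols; segmentation quality is out of scope), user network structure,
temporal dynamics (the validation is cross-sectional over cities),
geographic correlation between neighboring cities, and systematic
city-level reporting biases (the planted link is exact up to binomial
noise, whereas real message rates confound pollution with population,
platform penetration, and local news cycles). Recovery results on
generated corpora bound what the machinery can do when its model family is
correct; they say nothing about model misspecification on real text.

## Problem sizes used in validation

The shipped validation runs are scaled to desk hardware: correlation
recovery uses 74 cities × 5000 messages per city (fixed totals) with K=10
and 300 sweeps; topic recovery uses 3 planted topics, 1000 documents, K=3,
200 sweeps, averaged over 5 seeds; agreement checks use 2000 coded
messages; classifier checks use 200 labeled messages. These sizes were
chosen so the binomial attenuation of the empirical correlation stays
within the validation tolerances while the full suite completes in
minutes.

## Known limitations

* The sampler offers no out-of-sample (fold-in) inference; topic filters
  apply to the corpus the model was fitted on, which matches how the
  pipeline is used.
* The token criterion depends on one assignment state; rare-topic matches
  are sampler-noise sensitive. The θ-threshold criterion is the stabler
  alternative for content sampling.
* Keyword matching is exact token equality; substring matching on raw text
  (available behind a flag) changes semantics for languages without
  whitespace segmentation and is off by default.
* The applicability convention for per-code n is one of several defensible
  choices; agreement numbers are comparable only under a fixed convention.
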