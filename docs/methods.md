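# Methods

## The statistical problem

Dyadic data — one observation per ordered pair of actors — violate the
independence assumptions of ordinary regression because every pair of
dyads sharing an actor is correlated. The quadratic assignment procedure
(QAP) replaces parametric standard errors with a permutation null that
respects this structure: relabelling the *nodes* of a matrix (permuting
rows and columns simultaneously) preserves all within-actor dependence
while destroying any cross-matrix association. `netqap` implements this
family for the study design it was built around: a small school cohort in
which pupils' binary vaccination responsiveness is analysed as dyadic
*similarity*, regressed on friendship networks, structural network
mechanisms, and attribute homophily covariates.

## Data model and dyad ordering

All variables live on one roster of `n` pupils with a fixed node order.
Dyad-level vectors always use row-major ordering over ordered pairs
(sender, receiver) with the diagonal skipped, giving `n(n-1)` cells
(2352 for the default 49-pupil cohort). Networks are directed as
nominated; nothing is symmetrised. The diagonal of every dyadic matrix is
zeroed at construction so it can never leak into a statistic.

## Pseudo-network covariates

Categorical attributes (class, gender, ethnicity) enter as *match*
matrices (1 iff the two pupils share the category). Numeric attributes
(parent age, the two 7-point Likert relevance scores, the 1–5
medical-visit category) enter as *absolute difference* matrices, so
smaller values mean greater homophily. The medical-visit variable is an
ordinal category code; we treat it as numeric for differencing and note
that the resulting unit is "category steps", not visits. Difference
matrices are used on their raw scale by default; z-scoring is available
behind a flag but off, so coefficients stay interpretable in the
attribute's units. The binary response becomes an outcome-similarity
matrix (1 iff the two pupils reacted the same way), which for a binary
vector coincides with its match matrix — an identity the tests exploit as
an oracle.

## Structural mechanism covariates

The literature names reciprocity, triadic closure and preferential
attachment as tie-formation mechanisms but network packages operationalise
them differently, so each operator here has an explicit, recorded mode:

* **reciprocity** — cell (i, j) = adjacency(j, i), i.e. the transpose;
  the standard mutuality covariate. No modes.
* **closure** — default `count`: number of distinct third parties k with
  i→k and k→j (directed two-paths closing the dyad), bounded by n−2;
  `binary` thresholds at ≥ 1.
* **preferential attachment** — default `indegree`: the receiver's
  in-degree (popularity of the target); `degree_product` uses
  totaldegree(i)·totaldegree(j) for the undirected reading.

Mechanisms are always computed from the same network context as the model
they enter. Reports record the modes used.

## Permutation inference

* **Point estimates never depend on permutations.** MRQAP coefficients
  are OLS on the stacked dyad vectors; LRQAP coefficients are
  maximum-likelihood logistic estimates (Newton/IRLS, convergence
  tolerance 1e-9, step bound ±30 on the linear predictor; fits reaching
  the bound are flagged as possible complete separation). Odds ratios are
  `exp(b)` by definition.
* **MRQAP p-values** use double semi-partialing (DSP): predictor k is
  residualised on the remaining predictors, the residual matrix is
  node-permuted, and the pivotal t statistic of the permuted residual is
  recomputed with the other predictors held fixed. DSP retains nominal
  size under collinearity among dyadic predictors.
* **LRQAP p-values** default to response (Y) permutation: the similarity
  matrix is node-permuted and the full logistic model refitted; a
  DSP-style residual-permutation mode is available explicitly and never
  silently mixed with the default. The model p-value always permutes the
  response and compares the McFadden pseudo-R²; McFadden's measure is the
  likelihood-based choice and is named in the output metadata.
* **p-value convention.** Two-sided throughout, add-one rule (the
  observed statistic counts in its own null set), so p > 0 always. In
  exhaustive mode (all n!, permitted for n ≤ 8) the identity permutation
  plays the add-one role. The intercept receives no permutation p-value.
  One permutation sequence per model fit is reused across coefficients,
  reducing between-coefficient Monte-Carlo variance.
* **Numerical determinism.** Cross-products are computed with plain dot
  products, which are exact for the integer-valued matrices typical here,
  so exhaustive-mode correlations, OLS coefficients and p-values are
  bit-identical under simultaneous node relabelling. Logistic fits are
  iterative and accumulate in floating point, so in exhaustive mode the
  solver first sorts the stacked dyads into a canonical content order,
  restoring exact relabelling invariance at negligible cost for the tiny
  n involved. "As extreme as observed" comparisons use a 1e-12 tie
  tolerance so exact ties (common with binary matrices) count as ties
  regardless of rounding path.

## Synthetic cohort generator

The generator emulates the study conditions end to end so every pipeline
stage can be validated without access to survey data.

* **Attributes.** Each categorical column is a shuffled fixed multiset,
  so the configured marginals — 49 pupils in classes of 18/12/9/10
  (kept contiguous, as rosters are), 27 male / 22 female, 4 minority
  ethnicity, relevance-score counts (0,0,2,4,10,6,27) for pupils and
  (0,0,1,3,7,2,36) for parents, medical-visit counts (0,5,10,28,6) — are
  reproduced *exactly*, not in expectation. Parent ages are Normal(43.53,
  4.59²) truncated positive.
* **Networks.** Directed ties follow a logistic utility with class
  (+2.0 log-odds) and gender (+0.8) homophily, reciprocation of the
  current tie (+1.5), presence of a closing two-path (+0.8), and a base
  rate of −3.0 (school) / −3.5 (after school). The network is resampled
  in three full sweeps (the first sees an empty graph, so it is
  homophily-only); after-school ties get a +2.5 log-odds bonus where a
  school tie exists, reproducing the strong cross-context correlation of
  real cohorts. Out-degrees are capped at 8 (the nomination limit) by
  keeping the highest-probability ties. The defaults were chosen so the
  cap binds for most pupils, matching a questionnaire that invites up to
  eight nominations.
* **Outcomes.** A two-stage hesitancy-contagion process: one latent
  "index case" is placed uniformly at random, then a single contagion
  sweep lowers each pupil's outcome log-odds by `outcome_tie_effect`
  (default 3.5) per after-school contact (either direction) who is an
  index case, with index cases themselves anchored to refusal by a fixed
  ±4 log-odds pull. The intercept is calibrated by bisection so the mean
  outcome probability equals the 0.80 base rate. This plants a pocket of
  refusals around the index case — dyadic outcome similarity concentrated
  along after-school ties — which is what the regression is supposed to
  find. An earlier design that shifted log-odds by the *fraction* of
  contacts sharing the majority latent state proved statistically inert
  at this density: with ~12 contacts per pupil the fraction concentrates
  tightly and the planted dyadic correlation stays near zero at any
  plausible effect size, so the per-contact count form was adopted
  instead. Because seed placement ignores the network, setting the tie
  effect to zero makes outcomes i.i.d., and all downstream permutation
  tests are exactly calibrated under that null — the property the
  type-I-error suite checks.
* **Seeding.** All randomness flows from one config seed through
  documented per-stage substreams (0 cohort, 1 networks, 2 outcomes), so
  any stage can be reproduced in isolation and simulation outputs are
  byte-identical across runs.

## What the simulations do and do not show

Passing the recovery and calibration suites shows the estimators are
correct and well calibrated *for data with this generative structure*:
exact marginals, homophilous capped-out-degree nominations, and a single
localised contagion pocket. Real questionnaire data add features the
generator does not emulate — missing and inconsistent nominations,
ties to non-consenting pupils outside the roster, correlated attribute
noise, multiple or diffuse sources of hesitancy — so recovery rates here
are not a power claim about any real cohort.

## Problem sizes

Default simulated cohorts use the full study size (49 pupils, 2352
ordered dyads). Calibration experiments use 500 replicates of n = 20 with
200 permutations; recovery experiments use 100 replicates of n = 49 with
1000 permutations; enumeration checks use n = 5 (120 permutations).
Production fits default to 10,000 Monte-Carlo permutations.

## Known limitations

* Networks are restricted to the enrolled roster; nominations to pupils
  outside it are rejected at read time rather than modelled.
* Dyads are assumed complete: no missing-cell handling.
* The logistic solver flags (rather than penalises) complete separation;
  a Firth-type correction is out of scope.
* Which permutation scheme legacy network software applies to logistic
  network regression is not standardised; both defensible schemes are
  implemented as explicit modes, and reports record which was used.
* Exhaustive mode is limited to n ≤ 8 by factorial growth.
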