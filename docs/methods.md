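# Methods

This note documents the models, algorithms and design choices behind
`cessnet`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Tie construction

The event log is a table `(user_id, timestamp, action, channel, content_id,
thread_id, author_id)` with `action ∈ {view, post, respond, send_pm}` and
`channel ∈ {blog, group, wall, board, pm}`. A directed tie author → reader
is created at the reader's first view of any content by that author in the
blog, group or pm channels. Design choices:

- **One tie per ordered pair.** Degree counts distinct members; the channel
  and time of the *first* qualifying view are recorded. Ordering ties in
  time are broken by the event sequence number, so construction is
  deterministic for any input order.
- **Excluded channels.** Board views form no ties (author attribution on
  board pages is unreliable in the real system being modelled); wall views
  form no ties but do count as page views. The tie channel set is a
  function argument.
- **Excluded accounts.** Staff/bot ids are removed from both endpoints
  before any tie forms; they never enter network denominators.
- **Thread pages.** Each view row names exactly one content item and its
  author, so a view ties the reader to that author only. A log format in
  which one page view displays several authors' items would need one row
  per item shown; the construction is unchanged under that convention.

## Awareness

A tie Mary → John is *aware* when the chain completes inside one thread:
John's view of Mary's content at t₁, John's response in that thread at t₂,
and Mary's view of John's response at t₃, with t₁ < t₂ < t₃ under the
(timestamp, sequence) order. `aware_at` is the earliest qualifying t₃,
because that is the moment Mary learns she reached John; the aware
out-degree series bins on `aware_at`, not on the original tie formation.
Private-message conversations are threads of the ordered pair, and the same
chain applies.

## Weekly centrality series

Week `w ∈ {1..12}` for a participant spans `[registration + 7(w−1) days,
registration + 7w days)`. Series are cumulative counts of distinct
partners, hence non-decreasing, with `d_aware(w) ≤ d_out(w)` pointwise.
Ties to or from background (non-participant) members count: a participant's
audience is the whole community. The incremental implementation
(histogram of per-tie week indices, then a cumulative sum) is verified in
the tests against a from-scratch weekly network rebuild.

## Network summary

LSCC and shortest paths are computed with networkx; average path length is
the mean over all ordered pairs inside the LSCC. "Clustering coefficient"
is ambiguous between the average local coefficient and the global
transitivity ratio, so both are computed on the undirected projection; the
average local variant is the headline value and the choice is a function
argument. Degree distributions are reported as complementary cumulative
count tables for in-degree and aware out-degree.

## Sessions and utilization

Sessions are maximal runs of a user's page views with every internal gap
≤ 30 minutes ("more than 30 minutes" of inactivity splits, exactly 30 does
not). Duration is last view minus first view, so single-view sessions have
duration 0. Only view events define sessions; in the generator every
authored item emits a companion self-view one second later, so posting
always implies a page view. Utilization metrics are computed over the
participant's first 84 days (12 weeks, aligning the engagement window with
the centrality weeks; the alternative ~91-day calendar quarter would only
relabel the window). `total_posts` counts blog, group and board messages —
not private messages or wall posts — which is why a participant whose only
contribution is a wall post stratifies as passive; the classifier flags the
complementary degenerate case (posts without any recorded page view,
impossible under the generator but possible in raw logs) as `active` with
an audit column. "Days logged in" uses calendar days in the single
reference time zone of the site.

## Cohort stratification and group comparisons

Groups dichotomize both metrics at zero: non-users (0 posts, 0 views),
passive (views only), active (posts and views). Between-group tests are
dispatched by declared variable kind: one-way ANOVA for continuous baseline
scales, chi-square for categorical, Kruskal-Wallis for skewed utilization
counts, and an exact 2×k Fisher test for sparse indicators. The Fisher
test is enumerated directly (multivariate hypergeometric probabilities,
probability-ordering rule as in R's `fisher.test`) because available RxC
implementations are resampling-based and hence non-deterministic; the test
suite checks the enumeration against an independent oracle built on
scipy's multivariate hypergeometric pmf.

## Outcome models

- **Quartile scaling.** Continuous baseline/utilization covariates are
  centered at the group median and divided by (Q3 − median); quantiles use
  linear interpolation between order statistics (numpy default, type-7),
  documented because the scaled coefficients depend on the rule. A
  degenerate spread (Q3 ≤ median) leaves the covariate centered only, with
  a flag. Network terms are square-rooted but never scaled.
- **Stepwise selection.** Forward selection with backward pruning on Wald
  p-values at α = .10: add the smallest-p candidate below α, then drop any
  included term at or above α, iterating to a fixed point with candidate
  order breaking ties and a state-repeat guard against add/drop cycles.
  A forward-only variant is available. Candidates whose trial fit is
  degenerate (perfect separation) are skipped and reported.
- **Estimation.** Maximum-likelihood logistic regression with the HC0
  sandwich covariance. With one record per independent subject this equals
  the GEE working-independence robust covariance — the tests verify
  agreement with `statsmodels` GEE — so the simpler fit is used. Wald 95%
  intervals use the normal 1.96 multiplier. Non-convergence, coefficients
  above 50 in absolute value, or non-finite standard errors raise a
  separation error rather than returning garbage.
- **Group designs.** Passive users have zero out-degree by construction,
  so their model carries only the in-degree terms; active models carry all
  four network terms. Zero-variance columns (possible in small synthetic
  groups) are dropped before fitting.
- **Nine-tie extrapolation.** `OR(k) = OR(1)^√k`, confidence limits
  transformed endpoint-wise. The endpoint rule (rather than a delta-method
  interval on the transformed scale) is exact for monotone transformations
  of Wald limits.
- **AUC.** Ten-fold cross-validation stratified by outcome with a stored
  seed; held-out linear predictors are pooled into a single rank-based AUC;
  the apparent AUC comes from the full-data fit. Degenerate fold draws are
  re-randomized a bounded number of times.

## Synthetic-data generator

The generator emulates the study system — a mature cessation community
observed through a 12-week trial window — not any particular dataset.

- **Population.** `n_participants` trial members registering uniformly over
  a 28-day enrollment window, plus `n_background_members` established
  members (registered up to 28 days earlier) whose content participants
  read; ~1% of background accounts are staff/bots carrying the exclusion
  flag. Uniform arrivals are a stand-in; nothing downstream depends on the
  arrival law.
- **Activity.** Per-user rate multipliers λ ~ log-normal(−σ²/2, σ) with
  σ = 1.6 (E[λ] = 1), giving the heavy-tailed, mean ≫ median degree
  distributions characteristic of online communities. Views are Poisson
  with mean 6λ per 12 weeks; a fraction `lurker_fraction` = 0.66 of members
  never post (the passive-majority composition of such communities), and
  non-lurkers author 1 + Poisson(3λ) items, so the community's zero-post
  fraction equals the lurker fraction exactly. Activity is front-loaded
  within each user's window (time offset ∝ u², matching the documented
  first-week engagement peak), and views target recent content (an
  exponential look-back over the reverse-chronological item index, mean 100
  items). Both features are required for week-1 centralities to be
  non-degenerate; without them planted week-1 effects are unidentifiable.
- **Interactions.** A non-lurking reader responds in-thread with
  probability 0.15; the author then views the response with probability
  0.5, completing the awareness chain. Private messages are read by the
  recipient with probability 0.9, never before the recipient's
  registration.
- **Covariates.** Baseline survey variables (demographics, nicotine
  dependence, confidence and desire to quit, temptations, social support,
  personality, intentions) are drawn with means and spreads typical of
  adult smokers enrolling in internet cessation trials.
- **Outcome.** logit P(abstinent) = β₀ + Σ βⱼxⱼ where the xⱼ are the four
  square-root network features *computed by the analysis code path itself*
  plus named raw covariates. Defaults: β₀ = −2.2 (≈10% baseline abstinence),
  0.17 on √in-degree change, 0.26 on √aware-out-degree change, −0.02/year
  of age, 0.24 per unit confidence — per-√-unit odds ratios ≈1.19 and
  ≈1.29 on the network change terms, the magnitudes reported for such
  cohorts. Computing features with the same definitions used downstream
  makes parameter-recovery tests self-consistent; the planted truth is
  returned with the data.
- **Determinism.** One `numpy` Generator seeded from `seed` drives every
  draw; timestamps have second resolution with a sequence-number
  tie-break; identical config + seed reproduces the event log byte for
  byte.

**What the generator does not emulate:** message content and sentiment,
intervention arms, member churn and re-registration, bursty session-level
browsing (views are placed independently given the rate), multi-author
thread pages, and assortative partner choice (view targets depend on
recency and author activity only). Passing tests therefore demonstrate
correctness of the *algorithms* and calibration of the *estimators* under
a realistic but simplified data-generating process, not fidelity of any
particular real community's parameter values.

## Problem sizes in the test suite

Oracle-equivalence suites use 500 random digraphs of ≤ 12 nodes and 200
random event logs of ≤ 45 events — sizes at which exhaustive oracles are
trivially correct. Parameter recovery uses 100 replicate cohorts of 2,000
participants plus 1,500 background members, large enough that Wald
intervals attain near-nominal coverage while a full run of the suite stays
inside a few minutes on one core. The default generator configuration
(2,657 participants, 5,000 background members) mirrors the scale of the
motivating study's analytic sample.

## Known limitations

- Awareness requires the response to be the *viewed* content item; an
  author who revisits the thread but opens only other items does not
  complete the chain.
- The stepwise procedure inherits the usual post-selection inference
  caveats; reported p-values for selected baseline terms are conditional
  on selection, exactly as in the modelling tradition it reproduces.
- The exact Fisher enumeration is exponential in the number of columns and
  intended for 2×2 / 2×3 tables with modest margins.
- Average path length enumerates BFS from every LSCC node; for networks
  far larger than the default synthetic scale a sampled approximation
  would be preferable.
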