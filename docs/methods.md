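# Methods

This note documents the models, algorithms and numerical choices behind
`pollinet`, in the spirit of a statistical software appendix. It states
no empirical result beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Data model and filtering

A survey record is one plant × insect observation within one transect
survey, carrying visit count, floral units counted, inflorescence size
(mm² per floral unit), plant family and native status, and a two-level
habitat classification (broad class and subcategory, in the style of the
Irish Fossitt typology). Records are filtered before analysis:

- **Taxonomic resolution.** Both taxa must be resolved to at least genus.
  A name counts as resolved when it is nonempty and contains no stop word
  ("unknown", "unidentified", "indet."); aggregate names such as
  *Taraxacum agg.* are legitimate single taxa and are kept. The stop list
  is configurable.
- **Single-habitat surveys.** When a habitat comparison is requested,
  records from surveys tagged with more than one habitat subcategory are
  dropped entirely.
- Every dropped record receives exactly one logged reason; counts are
  conserved (kept + dropped = input).

Webs are built by summing visits per (plant, insect) pair within a
partition cell (full pool, habitat level 1 or 2, calendar month pooled
across years, or insect guild). Records with zero visits (a plant
surveyed but unvisited) never enter a web. All-zero rows and columns are
pruned at construction; an empty partition cell is absent from the
result rather than represented by a zero-size matrix. Dates map to ISO-8601
weeks, which are deterministic across locales.

**Floral display** is floral abundance × inflorescence size (mm²). The
display belongs to the plant-on-a-survey: when several insect records
repeat the same survey's floral count, it is counted once per
(site, date, transect, plant). Records with unknown inflorescence size
are excluded from display-normalized statistics only.

## Structural metrics

Connectance, web asymmetry and degree means follow the standard
definitions (see README). NODF uses the canonical strict decreasing-fill
rule: a pair of rows (or columns) contributes only when fills strictly
decrease — ties contribute zero, so any web whose rows and columns all
have equal fill scores 0. Presence is any positive weight; no cell-count
cutoffs. The implementation is order-independent (equivalent to sorting
by fill first) and is property-tested against a literal pairwise-overlap
enumeration and against independently computed reference values.

## Specialization: H2′ and d′

`H2 = −Σ p_ij ln p_ij` with `p_ij = a_ij/m`. H2′ rescales H2 between the
extreme entropies achievable by **integer** matrices with the observed
marginals:

- **Maximum entropy.** Entropy depends only on the multiset of counts,
  and maximizing it is a transportation problem with separable convex
  cost Σ n·ln n. A greedy construction (floor of the proportional
  expectation plus unit-by-unit placement on the least-filled eligible
  cell) is refined by negative-cycle cancellation on the residual graph
  over columns; for a convex separable objective the absence of a
  negative unit-cycle certifies global optimality. Refinement is applied
  to webs up to 2 500 cells; the greedy alone stands beyond that (it
  affects only the normalization constant of large webs).
- **Minimum entropy.** Minimizing entropy maximizes a convex function,
  so the optimum sits at a vertex of the transportation polytope and
  local-move certificates do not apply. Every vertex is reachable by
  repeatedly shipping min(r_i, c_j) for some pair order; a dynamic
  program over the multisets of remaining marginals explores all orders
  exactly for webs with m ≤ 24 and at most 6 rows/columns. Larger webs
  use a sort-and-concentrate greedy (largest transferable amount first,
  preferring pairs that annihilate a row and a column at once).

Both extrema were validated exact against exhaustive enumeration of all
integer matrices with fixed marginals on several hundred random small
marginal sets; the test suite re-runs a sample of that validation. If the
marginals force a unique distribution (H2max = H2min) the index is
reported as undefined, never as a silent zero. H2′ is clamped to [0, 1].

`d_i = Σ_j p′_ij ln(p′_ij/q_j)` with `p′_ij = a_ij/A_i` and availability
`q_j = B_j/m`; `d′_i = (d_i − d_min)/(d_max − d_min)` with
`d_max = ln(m/A_i)`. `d_min` is the divergence of the best integer
allocation of the species' total toward `q`: floor of the expectation
plus greedy unit increments by exact marginal KL cost — a one-dimensional
separable convex minimization, for which incremental greedy is exact.
Constraints from other rows of the matrix are not imposed (row-only
integer constraints), matching how the index is normally reported.
Species with `d_max = d_min` are flagged undefined. Specialization
asymmetry is Δd′ = mean d′(visitors) − mean d′(plants), over defined
species.

**Sample coverage** is the Good–Turing estimator; when the denominator
degenerates (n = 1 with a singleton) coverage reduces to `1 − f1/n`.

## Null models

The randomization preserves the observed dimensions, grand total m and
link count L ("connectance-preserving"), in two phases: (1) L distinct
cells are drawn with probability proportional to the product of row and
column marginal frequencies — weighted sampling without replacement via
the Gumbel trick — and the draw is rejected and repeated until every row
and column holds at least one link, with a cap of 10 000 attempts before
an infeasibility error; (2) each chosen link receives one visit and the
remaining m − L visits are distributed multinomially over the chosen
links with the same product probabilities. A web with L < max(P, A) is
infeasible by construction and is reported as such.

Two consequences worth knowing: for a strictly diagonal web every
feasible replicate is permutation-supported and therefore itself has
H2′ = 1, so the null spread is zero and z is undefined — detecting
specialization by z-score requires at least a few off-diagonal links.
And the z-score of a web drawn from the null generator against its own
ensemble is centred near zero but not unit-normal; the calibration tests
assert centring (|mean z| < 0.5) and coverage (|z| < 3 in ≥ 95% of
draws), not normality.

Ensembles are reproducible: replicate r draws from the deterministic
substream (seed, r), so results are independent of evaluation order. The
default ensemble size is 1 000. Both H2′ and Δd′ are evaluated per
replicate; z-scores use the sample standard deviation and are flagged
undefined when the ensemble has zero spread.

## Species roles and rankings

One-mode projections join two species of a guild when they share at
least one partner; centralities are computed on this unweighted graph
(betweenness as raw pair counts with fractional credit for ties;
closeness as (n_comp − 1)/Σ distances within the component, 0 for
isolated nodes — validated against exhaustive shortest-path enumeration).
Functional complementarity is the total branch length — the sum of merge
heights — of the average-linkage dendrogram over Euclidean distances
between species' interaction-frequency rows; the species-level
contribution is the leave-one-out reduction, floored at zero (the
network-level index has no published species decomposition, so the
decomposition choice is ours and is cross-checked by direct
recomputation in tests). Node longevity is the inclusive first-to-last
ISO-week span of a species' recorded activity, pooling years — "duration
of activity" read as a span, not a count of active weeks (the
alternative reading would differ for species with gaps). Visitation rate
is total visits over total floral display, undefined (and excluded from
ranking) without a positive known display.

Rankings use min–max feature scaling per metric (constant vectors map to
all zeros; scaling is monotone, so top-k membership is unaffected by
whether raw or scaled values are ranked). Seven metrics are ranked by
default — visitation rate, weighted and unweighted degree, longevity,
betweenness, closeness, functional complementarity — with the raw visit
total available as a configurable eighth; ties break by descending value
then ascending species label, for determinism. Family preference is the
difference between a family's share of the top-ranked species and its
share of the total floral display of the whole network (difference of
proportions, which closes to zero across families; a ratio would not).
Native/non-native contrasts use two-sided label-permutation tests
(10 000 permutations, seeded) with the Bonferroni-adjusted threshold
α = 0.05/7 ≈ 0.007 across the seven role metrics; mixed-effects
machinery with site/date random effects is deliberately out of scope,
so these p-values are design-agnostic permutation p-values, not model-based.

## The display–visitation diagnostic

The log-log attraction slope regresses, per plant species, the log
average visitor abundance per survey, `log((V_i + 1)/n_i)`, on the log
average floral display per survey, `log(D_i/n_i)`. Averaging per survey
is essential: totals conflate survey effort — a species blooming twice as
long accumulates roughly twice the visits *and* twice the display, which
masquerades as an attraction effect (per-species totals showed a bias of
about +0.08 on a planted slope of 0.4 in recovery simulations; averages
do not). The +1 offset keeps zero-count species finite and is documented
as part of the definition. The regression is ordinary least squares
(scipy `linregress`); at least three species with positive display and
nonzero display variance are required.

One limitation is inherent to visitation data: a plant-survey is
recorded only if at least one insect visited, so per-survey means are
zero-truncated and the simple species-level OLS attenuates the slope
when expected visits per survey are low. The recovery study therefore
runs at a visitation intensity high enough that nearly every blooming
plant-survey is visited; at low intensity the diagnostic should be read
as conservative.

## Cross-network comparison

External interaction matrices are read in the public-database convention
(rows = plants, labelled delimited text; a transposed orientation flag is
accepted), validated cell-by-cell, and summarized by the nine standard
measures. A focal network is flagged on a metric when it lies more than
two **sample** (n − 1) standard deviations from the reference mean —
sample SD because reference sets are small (n = 10 here); the reference
set always excludes the focal network. Richness-ratio summaries report
mean ± SE (sample SD/√n) of per-network visitor/plant ratios. The
packaged reference table carries the published summary statistics of ten
flower-visitor networks plus the Irish national web; the packaged Irish
table carries the per-habitat and per-month summaries. Two printed
full-network values differ between the habitat and the phenology
summaries of the source tables (plant richness 238 vs 239, plant
unweighted degree 6.41 vs 6.39); both rows are shipped as printed,
under `full_habitat_pool` and `full`.

## Synthetic data generator

The generator emulates the structure of multi-study national visitation
datasets: several level-2 habitats, each with its own (mostly unique)
plant pool; insects shared across habitats (generalist visitors);
per-species phenology windows inside weeks 14–44; lognormal inflorescence
sizes (μ = 3.0, σ = 0.8 on the log scale, mm²) and lognormal per-species
floral abundance (σ = 1, needed so the attraction regression has
x-variance); expected visits of insect j on plant i in one survey

    λ_ij = base_rate · activity_j · pref(guild_j, family_i) · α_i ·
           δ^[non-native] · (display / reference display)^β

with Poisson counts (negative-binomial behind an overdispersion switch).
Defaults: β = 0.4 (the magnitude of the reported per-species log-log
effect — recovery is always judged against the planted value, not the
reported one); δ = 0.45 (≈ e^−0.8, a non-native attractiveness deficit
of the reported order); guild richness shares 54.7/30.7/14.6%
(syrphid/bee/lepidopteran) with bee activity weighted 3× so bees
dominate visit abundance; ~32% of plants non-native; window width
1 + Poisson(5) weeks; base_rate 0.08, giving species visit totals of a
few tens over a season, the order seen in national webs. Preference
multipliers (syrphid→Asteraceae 4.0, bee→Fabaceae 4.0,
lepidopteran→Fabaceae 3.0) were calibrated once so the realized
top-rank over-representation is near the reported ≈ 20 percentage
points. Only positive visit counts become records, matching field data
in which unvisited plants are not recorded.

What the generator does **not** emulate: observer heterogeneity and
variable transect effort, within-season abundance trends, taxonomic
mis-identification, spatial autocorrelation among sites, and
year-to-year turnover. Passing recovery tests therefore demonstrates
estimator correctness under the stated model, not robustness to these
real-data features.

The recovery harness re-estimates, per replicate: β (bias, RMSE, mean
regression SE), the sign of the native/non-native weighted-degree
contrast, the sign of each planted family preference, and mean plant
longevity against the planted bloom window clipped to the survey horizon
(the observable quantity). Problem sizes used by the shipped recovery
study: 200 plants, 40 insects, 12 sites × 20 weeks, 50 replicates.

## Numerical choices and degenerate inputs

- Undefined metrics (empty guilds, degenerate marginals, zero null
  spread, singleton components) are surfaced as explicit `None`/flags or
  typed exceptions, never silent zeros — silent zeros would corrupt
  cross-network comparison.
- H2′ and d′ are clamped to [0, 1]; tolerances of 1e−12 guard the
  degenerate-marginals test, 1e−9 the cycle-cancellation stopping rule
  (float noise below that would cycle forever).
- All randomness flows from explicit seeds; ensembles and the CLI derive
  per-replicate substreams from (seed, replicate index).
- Tie-breaks are deterministic everywhere (alphabetical labels in
  rankings, stable sorts in allocations).

## Known limitations

- The H2 extrema beyond the exact-size bounds are heuristic; H2′ of very
  large webs may be normalized against slightly non-extreme bounds
  (both bounds err in the same conservative direction: a non-maximal
  H2max and non-minimal H2min shrink the denominator's reach).
- The rejection step of the null model can be slow or infeasible for
  webs whose link count barely covers their dimensions (near-permutation
  webs); the cap is deliberate and reported.
- Permutation contrasts ignore site/date dependence; with strongly
  clustered designs they are anti-conservative relative to a
  mixed-effects analysis.
- The attraction diagnostic attenuates under heavy zero-truncation (see
  above).
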