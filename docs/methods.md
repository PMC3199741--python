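# Methods

This note documents the statistical procedures implemented in
`fissionfusion`, the conventions adopted where the standard methods leave
choices open, and what the synthetic-data generator does and does not
emulate.

## Data model and aggregation

The observational unit is a *sighting*: one identified individual in one
field group on one calendar day. The sampling interval is the day. Within a
day, groups sharing at least one identified member are merged transitively
(connected components of the group-overlap graph) so that repeated encounters
with the same party are not double-counted; all members of a merged part are
associated for that day. Individuals whose entire seasonal record is a single
solitary sighting are dropped before any index is computed — one lone record
carries no association information and would otherwise only dilute the
permutation null.

Seasons are user-supplied calendars mapping (year, month) pairs to ordered
labels. Wet/dry month classification uses a strict "greater than threshold"
rule; rainfall units are carried opaquely (the threshold is in whatever units
the gauge record uses, configurable, default 120).

Cohorts: *residents* are present in every season and, within each season,
seen more than once or at least once in association; *core* individuals are
residents with at least `min_total_sightings` rows over the study (default
30). The two-stage filter controls the two noise sources of encounter data:
individuals ranging mostly outside the survey area, and individuals with too
few records for stable indices.

## Simple Ratio Index and its uncertainty

For a dyad (A, B), `SRI = X_AB/(X_t − X_n)` with `X_t` the number of sampling
days (days with at least one record — observation effort, not calendar span),
`X_AB` the days the pair shared a merged part, and `X_n` the days neither was
seen. The denominator is therefore the number of days at least one member was
observed, and the index estimates the probability the pair is together given
that it is observable.

Uncertainty is a delete-one-day jackknife: the day is the exchangeable unit,
so each replicate drops one day and recomputes the index;
`se² = (k−1)/k · Σ(SRI₍₋ᵢ₎ − mean)²` over the k replicates for which the
index remains defined. The jackknife is implemented behind a narrow interface
so an alternative closed-form estimator can be substituted.

## Permutation inference

**Within seasons (fill randomization).** The null hypothesis is that, given
each individual's number of sighting-days and each day's group-size
multiset, group composition is random. Replicates refill the observed
day x part-size skeleton from a shuffled multiset of individual-day tokens;
within-day duplicates are repaired by random pairwise swaps across days that
preserve both margins. Because duplicate-resolving swaps occasionally do not
exist (every id missing from the conflicted day can be absent from every day
where the duplicated id is free), the repair accepts a margin-preserving
*neutral* swap after repeated failures, which hands the duplicate to another
individual and lets the walk escape; a hard cap (10⁵ attempts) guards
genuinely infeasible margins. The test statistic is the mean SRI over all
dyads; the p-value uses the add-one convention
`p = (1 + #extreme)/(1 + n_perm)`, two-sided by default (distance from the
null mean), with one-sided alternatives available.

A structural point worth knowing: the total number of co-occurrence
pair-days, `Σ X_AB`, is *fixed* by the preserved margins. With perfect
detection every denominator equals `X_t` and the mean SRI is invariant under
the null — the statistic then has no power. Its power on real survey data
comes through the denominators: associated individuals share sighting days,
which is exactly what group-level (encounter) detection produces. The
calibration and power simulations therefore use detection < 1.

**Across seasons (Mantel).** Matrices are restricted to individuals seen in
both seasons; r is the Pearson correlation over matched off-diagonal entries;
the null simultaneously permutes rows and columns of one matrix; the p-value
is two-tailed with the add-one convention. 10,000 permutations by default.

Both tests are bit-reproducible given (input, seed, n_perm).

## Dyadic trajectory typing

Each core dyad with at least one non-zero seasonal SRI yields a vector of
per-season indices. Dyads with minimum SRI ≥ 0.3 in all seasons are *stable*
(type A) and set aside first. The remainder are clustered on *shape*:
vectors are z-scored per dyad and clustered with Euclidean K-means, which
is order-equivalent to correlation distance (for z-scored vectors,
`‖u − v‖² = 2d(1 − r)`). Flat non-zero vectors below the stable floor have no
shape under this metric and are reported as a separate "flat-unstable" bin
rather than forced into a cluster.

K is selected by maximizing the mean BIC over repeated K-means fits
(default 100 per K, K = 2…15), each from a random k-means++ initialization.
k-means++ seeding matters here: plain uniform random starts frequently
collapse two true shape clusters and the mean BIC then misranks the true K.
The BIC uses a spherical-Gaussian hard-assignment likelihood with a *pooled*
variance MLE `σ² = SSE/(d(n−K))` and parameter count `K(d+1)+1`; pooling
keeps the criterion finite when a run leaves a cluster nearly empty (a
per-cluster variance MLE degenerates to +∞ there). The final partition is
the best of 1000 restarts by within-cluster sum of squares.

Centroids (reported both z-scored and on the raw SRI scale for plotting) are
labeled by counting local maxima across the season sequence: one peak → type
B (temporary, with its peak season), two or more → type C (cyclic).
Endpoints count as peaks when they exceed their single neighbour. A maximum
must rise above the centroid's minimum by at least 25% of its range
(`min_prominence`, configurable): centroid means over finitely many noisy
members carry small wiggles on flat stretches, and without a prominence floor
those read as spurious peaks — endpoint seasons are especially vulnerable.

## Companion slots and turnover

Top-n associates (default n = 5) are the n highest-SRI partners per season;
zero-SRI partners never qualify, so the list can be short (the shortfall is
reported and the slot fractions keep the nominal `S·n` denominator). Ties at
the boundary are broken deterministically — more total sightings first, then
lexicographic id — for reproducibility.

An associate present in the top-n for m of the S seasons occupies m slots;
with `k_i(m)` such associates, `f_i(m) = k_i(m)·m/(S·n)`, and the population
mean `F(m)` summarizes fidelity. Under the null that each individual redraws
a uniform top-n each season, each partner's season count is Binomial(S, q)
with `q = n/(N−1)`, so `E[F(m)] = (N−1)·C(S,m)·qᵐ(1−q)^{S−m}·m/(S·n)`; at
N = 51, n = S = 5 the long-term share is `(5/50)⁴ = 0.01%`. The simulate mode
draws one ego per replicate (partners are exchangeable, egos independent).

Turnover counts, per individual, the associates retained in the top-n in
*every* season. The gregariousness trade-off regresses mean non-zero tie
strength on mean partner count across seasons (least squares; slope, R², p).

## Ego networks and the day bootstrap

Season networks connect every dyad with SRI > 0 (no weight threshold at this
stage); isolates remain as nodes. The five measures follow the classical
ego-network suite with the *ordered-pair* convention: Pairs = size·(size−1),
Ties counts each undirected alter–alter edge twice (ego–alter edges
excluded), so Density = Ties/Pairs equals the undirected alter–alter density;
2-Step Reach is a count of distinct individuals within two steps (not a
proportion). Density is undefined (NaN) for fewer than two alters and is
averaged over defined values.

Seasons are compared by bootstrap because ego measures of different
individuals share edges and are not independent. The resampling unit is the
sampling day — the natural exchangeable unit given day-long intervals. Each
replicate resamples the season's days with replacement and recomputes
SRI → network → cohort means. Contrasts use percentile intervals and a
two-sided bootstrap p with the add-one convention. Day resampling drops rare
co-occurrences, so bootstrap distributions of the count-like statistics sit
systematically *below* the observed values; the bootstrap mean is always
reported beside the observed statistic so this bias stays visible, and
between-season contrasts (both seasons biased the same way) remain
interpretable.

## Thresholded community structure

Girvan–Newman edge-betweenness removal ignores weights, so weighting enters
through a threshold sweep: at each τ on the grid 0, 0.02, …, 1 the network
keeps edges with weight *strictly above* τ (τ = 0 keeps every positive tie),
isolates are removed, and the full removal dendrogram is scored with
unweighted Newman–Girvan modularity. All partitions attaining Q_max are
returned; the recorded cluster count is their mean, with singleton clusters
not counted — together with isolate removal this makes the curve fall to
zero once τ exceeds the strongest ties. Q_max < 0.3 is flagged as "no
meaningful subdivision" but the partition is still returned. Betweenness ties
during removal are broken deterministically by canonical edge order
(independent of insertion order). The removal sequence itself is computed by
igraph's C implementation; consecutive grid thresholds selecting the same
edge set reuse the previous result, so a sweep costs one clustering run per
distinct edge set.

The *network structure curve* (mean cluster count vs τ) separates two
regimes: homogeneous tie strengths give a flat curve that collapses to zero
at the common weight, while two-level structure (strong within-unit ties over
weak between-unit ties) gives a peaked curve. Slope changes are localized by
a two-sided Mann–Whitney test comparing the curve increments in windows
(t−w, t] and (t, t+w] (default w = 0.2, i.e. 10 increments per side); when
both windows hold identical constant increments the p-value is reported as 1
(no evidence of change, and the rank test is undefined under total ties).

## Synthetic data generator

Each day, every pair of latent units fuses independently with probability
`p_between` (season-specific); connected sets of fused units travel as one
merged group. An unfused unit coheres with probability `p_within` or fissions
into parties with truncated-geometric sizes (mean `fission_mean_part`) over a
shuffled member order. Every realized group is then recorded with probability
`p_detect` — whole group seen or unseen, as in encounter-based surveys.
All randomness derives from one seed through `numpy` SeedSequence spawning,
with separate streams for population layout and survey realization.

Because all steps are independent coin flips, the per-dyad same-group
probability has a closed form (fission uses an exact DP for the same-party
probability; fusion uses the exact two-vertex connectivity probability of a
G(n, p) random graph), and the SRI's large-sample limit under group-level
detection is `c/(c + (1−c)(2−p_detect))` for same-group probability c. Tests
verify the observed SRI against this limit within 3 Monte-Carlo standard
errors at 2,000 simulated days.

Bundled configurations:

- `paper_like_config` — the default study: 24 units of 5–12 members
  (~200 individuals), five seasons (48/68/44/62/37 observation days, matching
  a two-year survey with a gap), `p_within = 0.2`, dry-season `p_between`
  0.03 vs 0.01, `p_detect = 0.1`, fission mean 2.5. Chosen once to reproduce
  the field regime: median observed group size 2–3, a core cohort of ~50 of
  ~200, inferred units severalfold larger than daily groups.
- `planted_units_config` — strong contrast for recovery tests: 10 units × 8,
  `p_within = 0.55`, `p_between = 0.05`, full detection, 300 days.
- `hierarchy_demo_config` — *heterogeneous* two-level structure (unit sizes
  4–10, imperfect detection): the spread of within-unit tie strengths is what
  produces a peaked structure curve with statistically detectable slope
  changes; a homogeneous-strength network is the contrast case.
- `null_mixing_config` — no social preference (singleton units, random
  pairwise fusion): used for type-I-error calibration of the permutation
  tests.

**What the generator does not emulate.** There is no home-range structure or
transient/resident heterogeneity, so nearly all simulated individuals qualify
as residents (field studies see far fewer); per-individual sighting counts
are binomial and hence narrower than real, heterogeneous detectabilities;
fusion merges whole unit-components, so long dry seasons can produce
occasional very large aggregations and a higher share of non-zero dyads than
sparse field matrices; individuals do not split time budgets among partners,
so the degree–strength trade-off is *not* planted (the analysis script
honestly reports its absence, and the trade-off detector is validated on
constructed matrices instead). Passing tests therefore demonstrate
correctness of the estimators and the recoverability of planted structure,
not that every distributional detail of field data is matched.

## Test problem sizes

The suite validates against brute-force oracles on enumerable instances
(leave-one-out jackknife, exhaustive modularity search on ≤ 9 nodes,
adjacency-matrix ego measures on 15-node graphs, hand-computed Pearson
correlations), calibrates both permutation tests on 400 null datasets at 200
permutations each (15 individuals, 30 days per dataset), and runs recovery at
10 units × 8 members × 300 days (community detection), 240 trajectories × 6
shapes (typing), and 20 seeded repetitions × 60 trajectories (K selection).
These sizes were chosen as the smallest at which the Monte-Carlo bands in use
(3 standard errors; ±0.02 around the nominal 0.05 size) are meaningful.
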