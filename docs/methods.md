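# Methods

## The model

`radialforage` models an animal foraging over a finite set of labeled food
positions in `R^d` (`d >= 2`; the packaged reference arenas are 2-D, 20
foods).  The behavioural parameter is the **foraging radial level** `k`:
a level-`k` forager evaluates a candidate food `e` by the k-th least
distance from `e` to the set `S` of uneaten foods,

    min_e^S(k) = k-th order statistic of { d(e, y) : y in S },

with the self-distance 0 counted at rank 1 whenever `e` itself belongs to
`S`.  Small values of this objective mark locally dense clumps of food —
the density-seeking intuition familiar from DBSCAN-style neighbourhood
counts, turned into a movement rule.  Two rules are implemented:

* **LMRFT** (long-term memory): the next food is the global argmin of
  `min_e^S(k)` over all remaining foods — a forager that remembers the
  whole arena.
* **SMRFT** (short-term memory): candidates are restricted to the radial
  ball `B_x^S(k)` of radius `min_x^S(k)` around the current position `x`;
  the starting food is empirical (for identification runs, the first food
  of the observed path).

After each step the eaten food is removed (`S_i = S_{i-1} - {x_i}`), so
the optimal path depends on the depletion history, not just the static
geometry.

Assumptions worth keeping in mind: perceived distances are Euclidean;
one food is eaten per step; there is no travel cost, risk or satiety in
the objective; and a single scalar level `k` stands in for perceptive
capability.

## Tie-breaking

Continuous coordinates make most ties measure-zero, with one important
exception: if `b` is `a`'s k-th nearest food and `a` is `b`'s k-th
nearest, both carry the identical score `d(a, b)`, so exact LMRFT ties
are *common* (the four-point worked example hits one immediately).  The
rules are:

* LMRFT step: lowest label wins (matches the worked example's choice).
* SMRFT step: nearer to the current position first, then lowest label.
* Rank matrices and relative-minimum achievers: ascending label.
* Strategy matching (argmin over levels): lowest level.

The rank-matrix rule "ascending column label" guarantees each row is a
permutation of `1..n`; the diagonal ranks 1 except in the degenerate case
of exactly coincident foods, which cannot arise at the packaged
coordinate precision.

## The structural metric

Paths are compared with a metric on strictly ascending vectors:

    d(v, w) = (||Δv|| + ||Δw||)/2 − ||Δz||,

where `Δu` is the consecutive-difference vector, `||·||` the Euclidean
norm, and `z` the *common parts*: all entries of either vector lying in
the overlap window `[max(v_1, w_1), min(v_m, w_n)]`, sorted and
deduplicated.  The printed source formula lost its radical signs in
typesetting; of the two candidate parses, only this one reproduces the
worked example's value 2.236759 (the root-mean variant
`sqrt((||Δv||² + ||Δw||²)/2) − ||Δz||` gives ≈ 2.245 and is kept behind
`parse="root_mean"` for sensitivity checks).

Property testing established that the aggregation is **not subadditive**:
on ~2% of random triples the triangle inequality fails, specifically when
the outer vectors' windows are disjoint (`z` empty, so nothing is
subtracted) while a middle vector bridges both.  Symmetry, identity,
nonnegativity, positive homogeneity and translation invariance all hold
(checked on 10^4 random pairs).  Path embeddings share the origin and
have strongly overlapping windows, so the failure mode is immaterial for
strategy matching, but "structural metric" should be read as
"structural dissimilarity" in full generality.

## Path embedding

A path enters the metric as its cumulative leg-distance vector with a
leading 0 — one entry per visited food, both compared paths sharing the
origin.  The embedding is a design choice (the source never states one);
the no-leading-zero variant is exposed via `leading_zero=False`.
Observed paths carry their recorded legs verbatim; modelled paths use
Euclidean legs recomputed from the arena.  This matters because the
packaged observed legs are *data*, decoupled from each agent's own arena:
in fact all three observed paths' printed legs turn out to be Euclidean
distances computed in the third agent's coordinate geometry (maximum
discrepancy 1e-3 across all 39 legs, i.e. coordinate rounding), so for
agents 1 and 2 they are inconsistent with their own arenas by
construction.

## What reproduces and what does not

The reproduction driver (`radialforage.reproduce_paper`, or
`radialforage reproduce-paper OUT`) recomputes everything from the
packaged arenas and reports per-item pass/fail:

* **Reproduces exactly**: all 12 LMRFT optimal label sequences (3 agents
  × levels 2–5, 14 steps), the worked-example metric value, the
  relative-minimum worked example, and the printed step scores and
  pairwise-distance anchors within 2e-3 (the arena coordinates are
  3-decimal roundings).
* **Does not reproduce**: the printed observed-vs-modelled structural
  distance grids, and with them four of the six published level
  selections (the SMRFT selections for agents 1 and 2 — level 5 — agree
  with the published conclusions under the default decode).  The
  default decode gives agent-1 LMRFT distances ≈ 8.8–9.1 (argmin level 2)
  against printed 21.2–22.9 (argmin 3).  A systematic search over decode
  variants — both formula parses, embeddings with and without the leading
  zero, sorted-leg and raw-leg vectors, geometry-recomputed observed legs
  (including the third agent's geometry), common parts built from leg
  sets — found none that matches the printed grid cell-by-cell; the
  root-mean parse lands in the right magnitude (≈ 21) but not the right
  level-to-level pattern.  The source is also internally inconsistent
  here: its own stated level selections contradict its printed distances
  for two of the six agent/mode combinations, and the SMRFT per-step
  table resists decoding at the available precision (its printed values
  are not leg distances in any agent's geometry).  The package therefore
  ships the validated decode and reports the discrepancy rather than
  fitting an embedding to the irreproducible grid.  SMRFT correctness
  rests on the worked example and on structural properties (every target
  inside its predecessor's ball, scores matching brute-force
  recomputation).

## Synthetic data

`SimulationConfig` defaults encode the reference conditions: 20 foods,
2-D, mean (0, 0), covariance `[[18, 5], [5, 9]]`, levels 2–5, 14 steps.
The covariance is a reading of a garbled printed parameter, chosen to
match the sample moments of the packaged arenas (x-variance ≈ 17,
y-variance ≈ 9, covariance ≈ 6); it is fully configurable and only
moment-level consistency is claimed.

`synth_observed_path` perturbs what an identification pipeline actually
consumes: optional adjacent label swaps (legs then recomputed from the
swapped sequence's geometry) followed by multiplicative log-normal leg
noise `exp(N(0, sd))` — multiplicative because recorded legs are
measurements whose error scales with length, and leg-level (not
coordinate-level) because empirical legs are data decoupled from the
arena.  What the generator does **not** emulate: spatially correlated
measurement error, non-greedy or exploratory detours, revisits, or any
within-path behavioural drift; passing recovery tests therefore show
identifiability under the model's own noise, not field realism.

With no noise, identification provably returns the generating level with
distance 0; this is verified across both modes, levels 2–5 and 50 seeded
arenas.  At 5% leg noise the generating level was recovered in 100% of
the same 200 level/arena replicates; the regression bound in the suite is
kept at the pre-registered ≥ 90%.

## Numerical choices

* All geometry in double precision; distance matrices symmetrized and
  zero-diagonal by construction; no epsilons in comparisons — ball
  membership and score ties compare values read from the same matrix, so
  equality is exact where it is meant to be.
* `k` exceeding the depleted subset size raises `RadialLevelError` rather
  than clamping; path construction validates `N <= n` and
  `k <= n - N + 1` up front (`ConfigurationError`).
* Degenerate metric inputs: length-1 vectors and empty/singleton common
  parts contribute norm 0.
* Reproduction tolerances: exact for label sequences and selected levels,
  2e-3 absolute for quantities recomputed from 3-decimal coordinates,
  1e-5 for the worked-example metric value.
* Test problem sizes: arenas of 20 foods and paths of 14 steps (the
  reference configuration); property tests use 10^4 random vector pairs,
  100 random domains of up to 12 points for the order-statistic oracle,
  and 50 seeded arenas per mode for recovery — sizes at which every
  check runs in seconds while still exercising all tie and depletion
  logic.

## Known limitations

* Single forager only; no collective foraging, interaction or avoidance.
* The objective ignores travel cost: LMRFT happily commutes across the
  arena for a denser clump.
* The metric's subadditivity failure (above) rules out metric-space
  machinery (e.g. triangle-inequality pruning) on top of it.
* Identification returns a point estimate (argmin level) without
  uncertainty; with 4 candidate levels and one path of 14 steps, nearby
  levels can sit within noise of each other.
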