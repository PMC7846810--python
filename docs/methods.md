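# Methods

## The inference model

The observable is a stream of reads `(timestamp, animal id, box id)` from
readers mounted at roost boxes. Experience is defined per (animal, box):
an animal is naïve at a box until the instant of its first read there and
experienced from then on. A leading-following (L/F) event at a box is a
joint visit of one experienced and one naïve animal; its
`time_difference` is the absolute gap, in fractional minutes, between the
two chosen reads.

Per box, the inference proceeds as follows. The follower slot of any
event is an animal's *first* read at the box (a repeat visitor is
experienced by definition and cannot be led there again). For a follower
first read at `t_f`, a leader candidate is any other animal, first read
at the box at `t_e`, possessing some read `t_l` with
`|t_l − t_f| ≤ lf_delay`, `t_l > t_e` and `t_l ≥ t_e + turnaround_time`.
Among a candidate's qualifying reads, the one minimizing `|t_l − t_f|`
is chosen, ties broken toward the earlier read (a determinism choice; the
field definition is silent on ties). One event is emitted per
(leader, follower) pair, so a joint arrival of k experienced and m naïve
animals yields k×m events.

Deliberate modelling choices, where the definitions leave room:

- **The leader's read may precede or follow the follower's.** A joint
  visit is defined by the absolute gap, not an ordering — a leader
  circling the box may be re-read after its recruit enters.
- **Turnaround is anchored at the leader's first read at that box**, not
  at its last event participation: experience is a per-box notion, and
  the parameter exists precisely so that an animal that just followed is
  not immediately promoted to leader.
- **The occupation cutoff is half-open**: reads strictly before the
  deadline instant (occupation date at `occupation_deadline` hours) are
  kept, reads at or after it are dropped — at that box, for the rest of
  the season, since an occupied roost keeps attracting swarming.

### Parameters

| parameter | unit | default | role |
|---|---|---|---|
| `lf_delay` | min | 5 | maximum leader/follower read gap of a joint visit |
| `turnaround_time` | min | 3 | minimum delay between becoming experienced and leading |
| `occupation_deadline` | hour of day | 5 | morning cutoff at occupied boxes (None disables) |

Defaults are the values the calibration procedure selects on realistic
simulated seasons; they should be re-calibrated per dataset.

## Calibration

There is no ground truth for which joint visits are genuine, so
parameters are selected from the shape of the time-difference
distribution itself. For each `(lf_delay, turnaround)` cell, events are
inferred at every deadline in the grid and all deadline pairs are
compared with a bootstrapped Wilcoxon rank-sum test: each of `n_boot`
(default 1000) replicates resamples both samples with replacement at
their original sizes and computes the asymptotic, tie-corrected
Mann-Whitney p-value; the replicate p-values are averaged. Both the
two-sided and the one-sided alternative (earlier deadline stochastically
smaller) are reported, along with the plain unbootstrapped p-values for
cross-checking. "Bootstrapped rank-sum" admits several readings
(resampling observations, ranks, or nights); resampling observations is
the one implemented, and the plain statistic is always exposed so the
choice is auditable.

Selection rule: per cell, the admissible deadline is the latest one not
significantly different (two-sided, default α = 0.05) from *all* earlier
deadlines — the earliest deadline is vacuously admissible; among
per-cell candidates, the tuple with the most events wins, ties going to
the smaller `lf_delay`, then the smaller `turnaround`. If every pair is
significant the earliest deadline is returned with a warning flag. No
multiple-testing correction is applied across the grid — the tests are
diagnostics feeding one decision, not a family of confirmatory claims.

## Networks and influence

Events aggregate into a directed weighted network (link
follower → leader, weight = event count, boxes disregarded). Density is
unique ordered links over n(n−1); both the unique-link count and the
total event count (weight sum) are always reported, since the two are
easily conflated. Strongly connected components are counted both
including and excluding singletons; the headline count excludes them
(an isolated vertex is trivially its own SCC and says nothing about
mutual leading), the inclusive count is in
`TopologySummary.n_scc_with_singletons`.

In-degree centrality is the weighted in-degree. Second-degree centrality
is `s(i) = k_in(i) + α · Σ_j k_in(j)` over the *distinct* followers j of
i — each follower's in-degree counted once regardless of how often it
followed i, which is what makes the α = 0 case collapse exactly onto
in-degree; an edge-weighted variant is available behind
`weight_by_edge=True`. The default α = 0.5 reflects the observed
dominance of chains of length ≤ 2 (see below) — indirect influence is
real but should be discounted, since aggregated networks cannot tell
whether a chain stayed on one roost.

Eigenvector centrality is defined here as the fixed point of
`x(i) ∝ Σ_{j→i} w(j,i) x(j)` on the raw weighted adjacency — no damping
or teleportation, so never-followed animals get exactly zero. It is
computed by power iteration from the uniform vector, max-normalized,
converged when successive iterates differ by < `tol` (default 1e-10,
`max_iter` 10000) in max norm. The iteration actually runs on **A + I**:
the identity shift leaves eigenvectors unchanged but makes the iteration
converge even when the recurrent part of the graph is periodic (on a pure
directed cycle the unshifted iteration rotates mass forever). On
reducible graphs with several competing recurrent classes the computed
vector is the (A + I)-power-iteration fixed point from the uniform start;
that fixed point is this package's definition of the measure.

Rankings use descending scores with average ranks on ties, and rankings
are compared by the Pearson correlation of the rank vectors (equivalently
the Spearman correlation of the scores).

## Chains

The event-chain graph has events as nodes and an arc e → e′ whenever
follower(e) = leader(e′) and t(e) < t(e′), where t(e) is the follower's
read time — the moment the information was received. Arcs strictly
increase in time, so the graph is acyclic and chains of k events are
directed k-node paths, counted exactly by dynamic programming
(paths-ending-at-event by length); sub-chains count separately, so a
linear cascade of m events contributes m−k+1 chains of length k. The
default cap of 16 covers observed chain lengths with margin. No
turnaround constraint is re-applied between chained events (they were
each validated at inference time), chains may cross boxes (the networks
aggregate over boxes, so must the chains), and when several datasets are
pooled the *counts* are pooled before frequencies are formed.

## The synthetic colony

`SimConfig` defaults describe a mid-sized maternity colony: 20 animals
(colonies run 10–50), 10 boxes, 60 nights, nightly activity in a
21:00–03:00 window starting 2008-05-01. Each night, each animal explores
a uniformly chosen box with probability 0.15; each experienced
(animal, known box) pair leads there with probability 0.04, recruiting
1 + Poisson(0.4) naïve followers whose reads trail the leader's by
truncated-exponential delays (scale 0.5 min, truncated at 2 min — no
field delay model exists; short delays dominating is the feature that
matters). A night-time group visit of ≥ 2 animals occupies the box with
probability 0.15 (occupation date = next morning), after which no
further events are planted there and, each subsequent morning, a
swarming burst fires: 40 reads by uniformly drawn animals spread over
140 minutes from 05:30. Swarming is phenomenological — a burst with wide
time spread, not a flight model — because only its statistical signature
(inflated time differences after the deadline) matters to the pipeline.
Spurious single reads occur at 0.05 per box-night. Timestamps are
emitted at 1-second resolution; a `reads_per_pass` knob duplicates reads
per pass (default 1), since real logger duplication behavior varies.

Within a box-night, visit clusters are anchored with pairwise spacing of
at least `min_event_separation` (30 min) plus the maximum follower
delay. With spacing far above `lf_delay` and delays below it, the
*separable regime* (no swarming, no noise, no occupation) makes every
planted event recoverable and no spurious pairing possible — inference
precision and recall are exactly 1 by construction. That regime is the
strongest test the generator supports, and its limits should be kept in
mind: real colonies do not space their visits politely, reader failures
and clock drift are not modeled, and exploration is spatially uniform
(no home-range geometry). Perfect recovery on synthetic data therefore
validates the *logic* of the inference rules, not their field error rate.

Scoring: an inferred event matches a planted one iff
(leader, follower, box) agree and both inferred read times fall within
the planted pair's read window (±1 s). Precision with zero inferred
events is reported as 1.0 with an explicit flag.

## Numerical and engineering choices

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; calibration derives one sub-seed per
  pairwise test from the master seed, so reports are reproducible and
  individual cells re-runnable.
- Recordings are sorted by (timestamp, animal, box) — a total,
  permutation-invariant order; duplicate rows are preserved (re-passes
  are real observations).
- Timestamps are ISO-8601 local wall-clock on disk (epoch-seconds via a
  dialect); no timezone arithmetic, as all readers in a study share one
  clock. Gaps are computed in fractional minutes, so second- and
  minute-resolution loggers are both handled.
- Degenerate inputs fail loudly and specifically: empty files, missing
  columns and unparseable timestamps raise distinct validation errors;
  density on < 2 nodes, rank correlation on zero-variance rankings, and
  non-converged power iteration (last iterate attached) are all
  signaled, never silently defaulted.
- Test-suite problem sizes (60-night seasons of ~20 animals, bootstrap
  grids of a few cells) were chosen to exercise every code path with
  comfortable statistical margins while keeping the default run fast.

## Known limitations

- Occupation dates are an *input* (from field day-roost checks); the
  shipped `estimate_occupation_dates` heuristic (first date with ≥ 2
  distinct animals read in the morning window) is a convenience and is
  flagged as non-canonical.
- Event assignment is hard, not probabilistic: a read either is or is
  not part of an event; no likelihoods over alternative pairings.
- Networks are aggregated over boxes and the season; no per-box layers
  or temporal snapshots.
- Whether an animal that just followed may lead within the same joint
  visit is governed entirely by `turnaround_time`; with a positive
  turnaround it cannot, which matches the parameter's stated purpose.
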