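# Methods

## Model and procedure

The unit of analysis is a per-subject structural connectome: an undirected
graph whose nodes are atlas parcels and whose edge weights are streamline
counts. Anatomically plausible resections are defined on a separate
*physical adjacency* graph G = (V, E): a resection is a connected set of
resectable parcels within one lobe, of size 1..K (K = 10 by default,
matching clinical practice of unilobar resections of limited extent).

For every resection the engine zeroes all edges incident to the removed
parcels and recomputes global efficiency

GE = (1 / (N(N−1))) Σ_{j≠k} 1/L_{j,k}

over the whole brain graph (both hemispheres plus non-resectable
subcortical nodes). The per-subject results, sorted by descending GE, form
the list L whose size strata S_n drive all downstream statistics.

### Conventions and ambiguities resolved

Several details of this procedure admit more than one reading; the choices
made here, and why:

- **Deleted nodes stay in the graph as isolates and N stays fixed.**
  Deletion is "zero the edges", which preserves a useful monotonicity: if
  A ⊆ B then GE after deleting B ≤ GE after deleting A, because removing
  edges never shortens a path. This invariant is property-tested. A
  `renormalize_n` option shrinks N to the surviving count for sensitivity
  analysis (and forfeits the guarantee).
- **Unreachable pairs contribute 0** (the standard efficiency convention,
  1/∞).
- **Edge length = 1/streamline-count** (`inverse-weight` mode), the common
  connectome convention that strong connections are short. Weighted GE is
  therefore not bounded by 1 when counts exceed 1. An `unweighted` mode
  (hop-count lengths, GE ∈ [0, 1]) is provided; the mode is recorded in all
  outputs.
- **Ties in the sorted list** are broken by (size ascending, lexicographic
  parcel tuple); all orderings in the package are deterministic so reports
  reproduce byte-for-byte.
- **Stepwise flags use strict inequality** — min GE over S_n must exceed
  max GE over S_{n+1}; exactly equal values count as mixed-in. The three
  named decline categories (perfect / partial / non-step) do not cover all
  flag patterns (e.g. step 1→2 stepwise, 2→3 not), so a fourth category
  "mixed" is used rather than forcing a misclassification.
- **Worst-deletion frequency tables** count each subject's single worst S_1
  deletion. Because "appears anywhere among a subject's worst deletions" is
  also a meaningful notion, a secondary membership table counts each
  parcel's appearance anywhere in the worst-by-size sequence.

## Enumeration

Generating deletion traversals from each starting parcel would emit every
permutation of the same parcel set; enumeration is therefore done over
*combinations* with the anchored-extension algorithm: connected sets are
grown from each anchor vertex, only vertices ordered after the anchor may
join, and a per-branch forbidden set (the anchor's ever-offered candidates)
guarantees each connected induced set is emitted exactly once. Equality
with a powerset-filter oracle is asserted in tests for every lobe up to 12
parcels and K ≤ 5. A configurable cap (default 2×10⁶ sets) warns before
runaway enumerations; `count_resections` gives a dry-run projection.

## Epicenters, D statistic, connectotypes

S_r is the smallest n such that the candidate parcel belongs to the worst
size-n resection; S_m = hop distance from the subject's worst single
deletion + 1 (forced by connectedness: a connected set containing two
parcels h hops apart has at least h + 1 members); D = S_r − S_m. Negative D
— arrival earlier than proximity permits — is the evidence that a candidate
is an epicenter independent of the subject's worst single deletion. The
package treats *negative* D as "early" because that is the direction that
falsifies the proximity null; descriptions that read larger D as closeness
have the sign transposed.

Connectotype assignment precedence: (1) the worst single deletion itself if
it is a candidate epicenter; (2) a candidate adjacent (one hop) to the
worst single deletion that joins it in the worst pair — small rank
differences between neighbouring parcels are noise at the scale of fiber
tracking, so such subjects collapse onto the adjacent epicenter; (3) the
candidate with minimal D, ties by smaller S_r then ID. The candidate count
per lobe defaults to 2 (configurable to 3); both values occur in practice
and no principled selection rule exists, so it is configuration.

## PageRank

The recursion places the teleport weight on d (PR = d/n + (1−d)·Σ PR_j /
outdeg_j), the transpose of the common damping convention; with the default
d = 0.15 scores equal standard 0.85-damped PageRank (cross-checked against
networkx in tests). Out-degree is the unweighted arc count by default, per
the formula; a streamline-weighted transition variant is available
(`weighted=True`). Dangling nodes link uniformly everywhere. Iteration
stops at L1 change < 1e-12 (max 1000 iterations; non-convergence raises
with the residual). Ranks are reported both per hemisphere (1 = highest)
and over the whole graph, since both views are of interest.

The synthetic-cohort experiments use the weighted variant: Poisson
expectations are positive for nearly every pair, so the binary adjacency is
near-complete and unweighted out-degree carries almost no signal there —
a property of the dense generator, not of empirical connectomes, whose
sparse matrices are served by the default unweighted form.

## Synthetic data generator

The generator emulates the *output scale and structure* of a tractography
pipeline, not tractography itself: ~300 000 streamlines per brain
(configurable), heavy-tailed weights via distance decay exp(−λ·hop) on the
adjacency graph, planted hub structure, and multiplicative inter-subject
noise. Per subject, each configured lobe's epicenter is drawn from the
connectotype mixing proportions; expected weight for pair (i,j) is
W·π_ij with π_ij ∝ exp(−λ·hop_ij)·b_i·b_j, where b = β on the epicenter,
√β on its adjacency neighbours (so worst resections form spatially coherent,
nested combinations), 1 elsewhere; realized counts are Poisson draws scaled
by a subject-level factor exp(N(0, σ²)). Pairs with no adjacency path
(contralateral parcels) are assigned hop = diameter + 1: interhemispheric
connections exist but are maximally decayed. Defaults: W = 300 000,
λ = 0.5, β = 2, σ = 0.1 — β = 2 is a moderate hub (twice the baseline
affinity) and σ = 0.1 gives ~10% between-subject volume variation, both in
the range of plausible tractography variability.

Randomness: one named integer seed; subject s uses the substream keyed by
(seed, s), so a cohort's first subjects are invariant to `n_subjects`.

What the generator does *not* emulate: geometric fiber trajectories,
distance-dependent tractography biases, false-positive bundles, or
topographic weight correlations beyond the decay kernel. Passing the
recovery experiments therefore shows the analysis chain is correct and
sensitive under a known generative model — not that real cohorts will show
equally clean epicenters.

### Full-scale atlas

The shipped 379-node atlas uses the authentic HCP-MMP1.0 area names (180
per hemisphere) grouped into the 8 analysed regions per hemisphere, plus 19
subcortical/cerebellar/brainstem components flagged non-resectable. Its
*adjacency is synthetic*: a within-lobe lattice (chain plus skip-one
chords) with links between anatomically bordering lobes, mirrored across
hemispheres. It provides realistic node counts and connected lobes for
scale testing; it is not a measured border graph, and analyses of real data
should supply their own topology JSON.

## Validation experiments and problem sizes

The experiments module replicates seeded cohorts at test scale — two lobes
of a 3×3 parcel grid per hemisphere (36 nodes), K = 6, 20 subjects — chosen
so a 50-cohort replication of the full pipeline completes in about a minute
on one CPU while every lobe remains small enough for exhaustive oracles.
Against the planted truth it measures: epicenter recovery rate (planted
parcel = cohort-modal worst deletion), connectotype assignment accuracy
under a 60/40 two-epicenter mix, the median worst-by-size nesting fraction,
the fraction of subjects with non-stepwise interleaving, and the PageRank
prediction rates. `scripts/acceptance.py` recomputes all of these from
scratch for a given seed.

## Known limitations

- GE is recomputed per resection (dense Floyd–Warshall below 129 nodes,
  per-source Dijkstra above); no incremental shortest-path updates, so
  full-scale sweeps with K = 10 over all lobes are compute-hungry — use the
  dry-run projection before launching them.
- The epicenter/connectotype precedence rules are one concrete reading of a
  qualitative narrative; rule (2)'s adjacency scope is a single hop.
- Lobe partitions are configuration, not derivation; the package never
  infers anatomy from imaging data.
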