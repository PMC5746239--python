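# Methods

## Model and procedure

A pregnancy's exposure is the mapping from the ten canonical gestational
reporting windows to the set of ATC level-5 codes reported in each. The
pipeline has four stages:

1. **Profile construction.** Long-format records (pregnancy × ATC code ×
   window) are validated against the window/questionnaire schema and
   collapsed to sets. One cross-questionnaire deduplication rule is
   applied: a medication reported both in Q1's open-ended "13 or later"
   window and in any Q3 window (13–16 … 29+) keeps only the Q3
   report(s), since Q3 re-asks the same calendar period at finer grain.
   This is the minimal rule preventing the most obvious double count;
   the full catalogue of reporting-overlap rules used on the original
   questionnaires is not public, so other overlaps are left as reported.
   All ten windows are kept as distinct coordinates — the observed
   distance ceiling of 60 (10 windows × per-window maximum 6) is only
   consistent with a 10-coordinate schema.

2. **Distance.** Medications are compared by the deepest shared ATC
   level, mapped to scores {0,1,2,3} via the configurable map
   {5→0, 4→1, 3→1, 2→2, 1→2, 0→3}. The available description of the
   score fixes only its endpoints (0 = same medication, 3 = nothing
   shared) and the ordering "paracetamol closer to opioids than to
   asthma medications"; the default map is the symmetric 4-value
   coarsening of the 5-level hierarchy consistent with those
   constraints, and the level at which scores 1/2 split (4/3 vs 3/2) is
   a documented reconstruction that can be swapped out through the
   `score_map` parameter. Truncated codes (e.g. a reported `N02A`) are
   compared on their available prefix, so only identical level-5 codes
   score 0.

   Per window, sets are aggregated by the symmetric best-match mean:
   `contribution(A→B) = mean over a of min over b of s(a,b)` with
   min over an empty B = 3 and mean over an empty A = 0, and the window
   dissimilarity is `contribution(A→B) + contribution(B→A)` ∈ [0, 6].
   The pregnancy distance is the sum over the ten windows, ∈ [0, 60].
   Sum-based (`best_match_sum`, unbounded) and max-based (`hausdorff`,
   window range [0, 3]) aggregators are available for sensitivity
   analysis. Best-match set measures do **not** satisfy the triangle
   inequality; nothing downstream assumes it.

3. **Clustering.** Agglomerative clustering with the centroid criterion
   applied directly to the squared input distances through the
   Lance–Williams recurrence
   `D²(k, i∪j) = (nᵢD²(k,i) + nⱼD²(k,j))/(nᵢ+nⱼ) − nᵢnⱼD²(i,j)/(nᵢ+nⱼ)²`.
   The input distance is not Euclidean, so this follows the standard
   convention of generic linkage implementations on condensed matrices;
   dendrogram inversions can occur and are legitimate. Recorded heights
   are square roots of the minimal squared centroid distance (the
   alternative — recording the squared distances themselves — would only
   rescale the dendrogram); a small negative recurrence output, possible
   on non-Euclidean input, is clipped to 0 before the root. Ties are
   broken by the lexicographically smallest cluster-id pair, making the
   merge sequence fully deterministic and permutation-equivariant up to
   ties. Flat clusters are extracted either by undoing the last k−1
   merges *in merge order* (robust to inversions) or by a height
   threshold interpreted as connected components of sub-threshold
   merges. k is always a user input: automatic flat-cut criteria produce
   very unbalanced cluster sizes on cohort-like data, so only a
   largest-gap height diagnostic is provided. Validation uses the mean
   silhouette coefficient `(b−a)/max(a,b)` on the precomputed distances,
   with singleton clusters contributing 0.

4. **Summaries.** Per cluster: n, percent of cohort, mean medication
   exposure (mean over members of the per-window average medication
   count, paracetamol included — whether the index drug itself should
   count is ambiguous in the source material; including it is the
   default and the denominator is fixed at 10 windows regardless of
   gestational length), the 10-window mean-exposure trajectory,
   paracetamol-only counts (members whose entire reported exposure is
   exactly {N02BE01}), a dominant-ATC-class flag, and covariate
   cross-tabulations. Percentages are computed on non-missing
   denominators and missing counts are reported per variable; missing
   covariates never exclude a pregnancy from clustering. Health
   conditions are covariate-table fields; an ATC-derived proxy
   (N06A/N05 → mental illness, R03 → asthma) exists for synthetic runs
   only. No inferential tests across clusters are provided.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `score_map` | {5:0, 4:1, 3:1, 2:2, 1:2, 0:3} | deepest-shared-level → dissimilarity |
| `aggregator` | `best_match_mean` | per-window set aggregation |
| `k` / `height` | — (user input) | dendrogram cut |
| `dominance_ratio` | 2.0 | cohort-enrichment factor for the dominant-class flag |
| `min_dominant_share` | 0.25 | minimum within-cluster exposure share for enrichment-based dominance |
| `paracetamol_window_rate` | 0.55 | generator: per-window probability of the index drug |
| `persistence` | 0.0 | generator: probability a window's medication carries into the next |

## The synthetic cohort generator

The generator emulates the *structure* of a questionnaire-based
paracetamol cohort: every pregnancy reports `N02BE01` in ≥ 1 window
(profiles with no sampled paracetamol get it force-inserted into one
uniformly chosen window), co-medications are Bernoulli draws per
(medication, window) with cluster-specific rates, covariates come from
cluster-shifted categorical distributions over the standard
maternal/child table vocabulary with realistic missingness (0.1%–5% per
variable), and the Q1-"13+"/Q3 deduplication rule is applied at
generation time so generated cohorts are fixed points of the profile
builder (one visible consequence: trajectories dip at window index 3,
which retains only medications *not* re-reported in Q3).

The bundled `five_cluster_template` plants five groups whose mixing
weights (19/4900/2643/1811/405 of 9778 ≈ 0.2/50.1/27.0/18.5/4.1%) and
expected mean exposures (2.8 / 0.7 / 1.0 / 1.3 / 1.8 medications per
window) mirror the reference cohort's cluster shape: a tiny
everything-in-high-intensity group, a low-intensity majority, a
moderate group, an antidepressant-marked (N06A) group, and an
asthma-medication-marked (R03) group. Two structural choices matter:

* **Signature medications are chronic.** Each non-baseline cluster uses
  its marker class at a high per-window probability (0.95). Under a
  best-match distance, a cluster that differs from the baseline only in
  *intensity* at moderate rates is unrecoverable in principle: with a
  signature code at per-window rate p, the expected within-cluster
  mismatch per window is 2p(1−p) versus p between clusters, so within
  exceeds between for p < 1/2 and the two only separate clearly for
  p ≳ 0.75. Recoverable planted structure therefore requires class-mix
  contrasts with near-chronic use, which is also the clinically
  realistic pattern for antidepressants and asthma controllers. Real
  cohort clusters that differ mainly in intensity are *not* this
  cleanly separated; passing recovery tests on the template shows the
  pipeline recovers strong class-mix structure, not that real cohorts
  contain it.
* **Rates are solved for the post-deduplication means.** Because the
  window-3 rule removes re-reported medications, per-window rates were
  chosen so the *expected post-dedup* mean exposures land on the target
  values (e.g. signature rate 0.95 yields ≈ 0.86 effective windows per
  10); empirical means at n = 2000 are 2.80 / 0.69 / 1.02 / 1.28 / 1.79.

Bernoulli independence across windows is a simplification of serially
correlated real use; the `persistence` parameter adds a Markov
carry-over for sensitivity checks (it raises marginal rates, so it is
off by default). The default catalog has 21 level-5 codes across the
relevant classes; `expanded_catalog` scales it to hundreds of rare codes
to emulate cohorts reporting > 300 distinct medications. The generator
makes no attempt to match real prevalences beyond the cluster shape
described above, and does not simulate enrolment or exclusion flows.

## Numerical choices and problem sizes

* Distances accumulate in double precision; matrix entries are
  bit-for-bit reproducible for a fixed input order. The matrix is built
  per window over *distinct* window sets (a set-vocabulary
  factorization), so typical cohorts cost far less than n² set
  comparisons; 10⁴ profiles (~5×10⁷ pairs) fit the O(n²) memory
  contract.
* The linkage keeps nearest-neighbour bookkeeping per row: typical cost
  near O(n²), worst case O(n³). A 2000-leaf tree builds in seconds.
* Test and validation sizes: unit tests use cohorts of 60–500 and
  matrices of n ≤ 50 against brute-force oracles; the recovery check
  runs the full pipeline at n = 500 and the scale check at n = 2000 with
  a > 300-code catalog.
* Degenerate inputs: all-zero distance matrices merge at height 0 in
  lexicographic order; empty window sets follow the stated empty-set
  conventions; a cohort of identical profiles yields a zero matrix and a
  single cluster at any height cut.

## Known limitations

* The exact original dissimilarity algorithm and deduplication rule
  list are not public; both are reconstructions constrained by the
  printed endpoints, the 0–60 distance range, and the stated similarity
  ordering, and both are configurable.
* Centroid linkage on a non-Euclidean distance admits inversions;
  heights are not monotone and flat cuts by k are defined by merge
  order, not height.
* Mean exposure counts distinct medications per window — with no dose
  data, "intensity" means breadth × duration of use, not dose.
* The silhouette is computed on the same distances that produced the
  clustering; it measures internal consistency, not external validity.
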