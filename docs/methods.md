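# Methods

This note documents the models, numerical choices and synthetic-data design
behind `volcbir`, and what the test suite does and does not establish about
behaviour on real imaging data.

## Retrieval model

**Slice search.**  All embeddings are L2-normalized at ingest (a zero or
non-finite embedding is rejected rather than silently coerced, since the
normalization divides by the norm), so the inner product equals cosine
similarity and the index can use an inner-product metric throughout.  The
`exact` backend scores every indexed slice and is the reference; the `ann`
backend is a graph-based approximate index (NN-descent via pynndescent)
whose candidate sets are approximate but whose returned scores are
recomputed exactly and ordered under the same tie rule, so only recall is
at stake.  Defaults: graph degree 32, construction breadth 100, query
over-fetch derived from a search breadth of 128; on the retrieval workload
(slice embeddings of held-out volumes over a ≥5,000-slice database)
recall@20 against the exact backend measures ≥0.95.  Ties in cosine are
broken ascending by `(volume_id, slice_index)`; rankings are therefore
invariant to indexing order, which the tests assert.

**Hit-table aggregation.**  One row of up to `n_neighbors` (default 20)
hits per query slice.  Multiple hits of the same volume — whether from one
row or many — all contribute to Count-base and Sum-Sim; summed similarity
is accumulated with exact float summation over sorted addends so aggregate
scores are bit-identical under any row/hit reordering.  Aggregate ties fall
back to higher summed similarity, then ascending volume id.

**C-MIR re-ranking.**  `RS(C) = Σ_i max_j ⟨q_i, c_j⟩` over the *full*
candidate matrices (not only the hit slices), fetched one candidate at a
time so the peak working set is one query matrix plus one candidate matrix.
Re-ranking permutes the incoming top-M list (default M=20) and never changes
its membership; equal rank scores preserve the incoming order (stable
re-rank).  The first-stage list re-ranked by default is Count-base; this is
configurable (`cmir_first_stage`), as any aggregation can seed the
candidate set.  Since RS never reads the database slice masks, C-MIR output
is identical between segmentation-restricted and unrestricted databases
whenever the first-stage candidate sets coincide — the tests construct this
case with databases small enough for the top-M list to cover every hit
volume.

**RRF.**  `RRF(V) = Σ_{ℓ=1..3} 1/(k + rank(V, L_ℓ))` with 1-based ranks
over exactly the three aggregation lists and smoothing `k = 60` (the
standard constant); a volume absent from a list contributes a zero summand.
Output order depends only on ranks, never score magnitudes.

## Evaluation protocol

Relevance is judged from the viewpoint of a *target organ*: a volume
acquired for another organ's task counts as negative for the target organ
even if its own organ carries a tumor (its target organ is healthy).
Flagging requires equal effective tumor status; staging requires equal
stage for positives (strict equality — adjacent stages are not partially
relevant) and equal status otherwise.

P@k uses k ∈ {3, 5, 10}; lists shorter than k count missing slots as
non-relevant.  AP is the recall-weighted precision sum over the top-10
list, `AP = Σ_n (R_n − R_{n−1}) P_n`, with the recall denominator equal to
the number of relevant items *within the top-10* (0 relevant ⇒ AP = 0).
This top-10-local normalization matches AP magnitudes in the 0.6–0.9 range
reported for archive-scale retrieval; normalizing by all relevant database
volumes (often hundreds) would collapse AP towards zero and is not what
retrieval summaries of a fixed-depth list report.  An algebraic identity —
AP equals the mean of precision at relevant ranks — is property-tested on
random judgments.

Experiments repeat over seeds (default 10): per seed the cohort is
regenerated, the split resampled, the index rebuilt, and every query
evaluated under every method; per-seed mean tables feed two-sided Wilcoxon
signed-rank comparisons of per-seed mean AP.  Zero differences are dropped
(the classical treatment; all-zero ⇒ p = 1 with a warning).  For n ≤ 25
retained pairs the p-value comes from the exact tie-aware null distribution,
computed by dynamic programming over doubled midranks (each sign pattern
equally likely; doubling makes midranks integral), with
`p = min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)))`; larger n uses the normal
approximation with tie correction.  The exact branch is verified against
full `2^n` sign enumeration and, on tie-free samples, against an
independent implementation.

One global seed fans out to per-stage seeds (cohort, split, index) through
`SeedSequence([seed, stage_code])`, so any run is reproducible from a
single integer; all derived seeds stay below 2³¹.

## Cohort construction

Splits are at the volume level — no volume contributes slices to both
sides.  Per target organ, positives are sampled per stage stratum:
`max(1, ⌊0.25·|S| + 0.5⌋)` of each non-empty stratum (rounding half up; the
25% fraction is configurable), and an equal number of negatives is drawn
from volumes containing the organ tumor-free, preferring other organs'
task volumes (a liver-task volume with healthy lungs is a valid lung
negative).  Within one seed sampling is without replacement (a query set
with repeated volumes is meaningless); across seeds draws are independent,
so repetition query sets may overlap.  The query set is identical between
the with- and without-segmentation database configurations; only the
database's searchable slice masks change (segmentation restricts each
database volume to the slices showing the target organ).  The
organ-agnostic configuration pools per-organ query samples over one unified
all-slice database, sampling organs in sorted order and never assigning a
volume to two organs' query sets.

## Synthetic cohort generator

The generator plants, directly in embedding space, the statistical
structure the pipeline is sensitive to.  Its geometry:

* **Orthonormal class axes.**  One organ axis, one tumor axis, and one axis
  per stage, per organ, all drawn as a random orthonormal frame (QR of a
  Gaussian matrix).  Exact orthogonality matters: merely-random directions
  have cosines ~1/√L, and that residual correlation deterministically
  funnels the forced top-20 hits of off-target query slices onto one
  arbitrary class cluster, distorting count-based rankings.
* **Slice signal.**  A volume of organ `o`, class `c` carries
  `separation · (a_o [+ u_o + stage_amp·v_{o,s}])` on the slice slab where
  its organ appears; each volume also shows a couple of *other* (healthy)
  organs on disjoint slabs stacked in a fixed anatomical order, the way an
  axial CT traverses organs at different slice ranges — and this is what
  makes cross-task negatives available to the sampler.  Slices outside any
  slab are pure noise.  The primary organ spans 75% of the volume by
  default: a margin analysis of the late-interaction score (organ-match
  gap `n_organ·(1 − cos(tumor, healthy))` against the bonus a shared
  healthy-organ slab contributes) requires the primary slab to dominate,
  and 0.75 yields a ratio ≈1.8.
* **Sub-noise stage structure.**  Stage axes enter with amplitude
  `stage_spread · noise · separation/(1 + separation)` — stage separation
  grows with the signal but *saturates below the slice-noise floor*
  (`stage_spread < 1`).  With only a handful of same-stage database volumes
  and 20 hits per slice, any super-noise stage gap would fragment hit
  neighbourhoods into same-stage islands and cap flagging precision for
  every method at every separation; sub-noise stages keep each organ's
  tumor cluster retrievable as a whole while leaving a mild same-stage
  bias, reproducing the empirical ordering that staging is intrinsically
  harder than flagging.
* **Within-volume correlation.**  Slice deviations follow a stationary
  AR(1) process with coefficient `within_volume_drift` (default 0.3), so
  adjacent slices correlate as neighbouring anatomy does.
* **Separation scales amplitude.**  At `separation = 0` embeddings are
  isotropic noise — organs and classes indistinguishable, retrieval exactly
  at chance — which makes the chance-level check clean; recovery of the
  planted signal is monotone in separation and saturates quickly (partial
  recovery is visible near `separation ≈ 0.05` at the default noise 0.2).

Defaults (the "desk preset"): L = 64, four organs × (tumor-free + S1–S4)
× 6 volumes, 20–60 slices per volume (≈5,000 slices), separation 1.5,
noise 0.2.  Archive-scale cohorts (10⁵ slices) are a configuration, not a
different code path.  The monotone-recovery check uses separations
{0, 0.05, 1.5} at fixed noise; the near-perfect-recovery condition uses
separation 6 with noise 0.05 on the without-segmentation organ-specific
configuration, where all five methods reach mean flagging AP ≥0.95 over
five seeds.

What the generator does *not* emulate: pixel content, physical tumor size
(the quantity clinical staging actually measures), scanner and protocol
effects, patient-level correlation between volumes, or the embedding
geometry of any particular extractor.  Passing tests therefore establish
the correctness of the retrieval machinery and the qualitative behaviour
of the methods under planted structure — not performance levels on real
archives, which depend on the chosen feature extractor.

## Problem sizes

The default test and acceptance runs use desk-scale cohorts (≈40–140
volumes, ≈1,500–5,600 slices), 5-seed repetitions for recovery checks, a
reduced two-organ cohort for the 10-seed protocol-shape check, 500–1,000
random matrix pairs for the late-interaction oracle, 100–200 queries for
the search oracles, and 100 samples for the Wilcoxon enumeration check —
sizes at which every check is exact or statistically stable while the whole
suite runs in minutes on one CPU.

## Known limitations

* Count-base/Sum-Sim depend on the hit-table depth (20): volumes beyond
  every slice's top-20 receive no evidence at all, an intrinsic truncation
  of hit-table CBIR.
* C-MIR's whole-volume rank score rewards shared healthy anatomy between
  query and candidate; with small databases this can promote negatives
  that share context over positives that do not — visible in the generator
  when the primary-organ span is made small.
* The ANN backend's recall guarantee is empirical and workload-dependent;
  adversarially off-manifold queries (random unit vectors far from the
  data) show materially lower recall than slice-embedding queries.
* Applying C-MIR as a primary retrieval method over a full database is out
  of scope (memory scales with the whole database's matrices); it is a
  re-ranker over top-M candidates.
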