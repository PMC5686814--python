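# Methods

## Model

A chromosome's Hi-C data is an N×N symmetric non-negative matrix `M` of
normalized contact frequencies between fixed-size bins (normalization is
assumed done upstream; the readers reject NaN, negative and materially
asymmetric input, and average away asymmetries below 1e-6 of the matrix
maximum). The working assumption is the defining property of a TAD: bins
inside one domain share a similar genome-wide contact profile, distinct
from the profiles of bins outside it. TAD calling therefore reduces to
clustering the per-bin profiles and reading domains off as runs of equal
labels along the diagonal.

### Features

Bin `i` is represented by the concatenation of row `i` and column `i` of
`M` (length 2N). After symmetrization the two halves are identical, which
leaves every pairwise dissimilarity intact up to a constant factor; the 2N
layout is kept because it is the form the method is defined in, and it
costs little. Bins whose entire row is zero (gaps) get no feature vector
and are excluded from clustering — they would be labelled gap regardless,
and clustering them would only distort centroids. An optional `log1p`
transform is available but off by default: profiles are clustered as raw
normalized counts.

### Clustering

* **K-means** (`KM`) is a Lloyd iteration generalised over the metric:
  assignment by nearest centroid under euclidean, city-block or Pearson
  (`1 − r`) dissimilarity; centroid update by the minimiser of the
  within-cluster sum for that metric — coordinate-wise mean for euclidean
  and Pearson, coordinate-wise median for city-block. Initial centroids
  are `k` distinct rows drawn by the seeded generator; 10 restarts by
  default, best run by within-cluster sum of distances. A cluster that
  empties is re-seeded with the point farthest from its centroid, stealing
  only from clusters that keep at least two members so the fix cannot
  cascade. Constant profiles under the Pearson metric are treated as
  maximally uncorrelated (distance 1) instead of failing mid-run.
* **Hierarchical** (`HC`) is scipy agglomerative clustering on the
  condensed dissimilarity matrix, cut at `k` clusters. Average linkage is
  the default because it is defined for arbitrary dissimilarities
  including `1 − r`; single, complete and (euclidean-only) Ward are
  accepted.
* **EM** is a diagonal-covariance Gaussian mixture (scikit-learn) with
  K-means initialisation, convergence at log-likelihood change < 1e-6 or
  300 iterations, hard assignment by maximum posterior, and component
  variances floored at 1e-8 of the overall data variance so duplicate
  rows (zero-noise fixtures) cannot underflow. EM carries no metric
  choice: the Gaussian model fixes the geometry.

Labels are always relabelled 0..k−1 in order of first appearance, making
runs deterministic given the seed and invariant to internal label
permutations.

### Choosing K

K is the method's only parameter. Three policies:

1. **Size rule**: `K = round(sqrt(n/2))`, floored at 2, from the
   rule-of-thumb that a dataset of n points holds about `sqrt(2n)` points
   per cluster. Round-to-nearest is used (n = 30 gives 3.87 → 4; ceiling
   would agree here but biases upward for large n).
2. **Window search** (default): every K in
   `[max(2, K_est − 10), min(n − 1, K_est + 10)]` is clustered and
   extracted, and the K whose TAD set has the highest mean quality wins;
   ties go to the smaller K.
3. **Elbow**: for K in a range (default 2..10) the percentage of variance
   explained, `100 · (1 − within/total)`, is computed with squared
   member-to-centroid distances under the active metric. The elbow is the
   K with the largest drop in marginal gain,
   `2·curve(K) − curve(K−1) − curve(K+1)`, with `curve(1) = 0` (one
   cluster explains nothing) so the lower end of the range is eligible;
   ties go to the smaller K. On a curve with no pronounced bend (a single
   blob) the argmax is still returned but is weakly determined. The elbow
   is practical for small matrices; the window search is the default for
   real chromosomes.

### Cluster-quality indices

The Davies-Bouldin index is the mean over clusters of
`max_{j≠i} (d_i + d_j) / d_ij`, with `d_i` the mean member-to-centroid
distance and `d_ij` the centroid separation; lower is better; coincident
centroids are a hard error. The Silhouette index uses
`s_j = (b_j − a_j)/max(a_j, b_j)` per point (singletons score 0) and
averages per-cluster means over clusters, staying in [−1, 1]. Both outer
averages run over *clusters*, not points — the standard-literature
reading of the defining formulas, which are ambiguous on this point.

### TAD extraction and scoring

Runs of equal labels become segments that tile the chromosome. Gaps stay
gaps; a segment is a TAD iff its span reaches the minimum domain size —
`bins · resolution ≥ 180 kb` when the resolution is known (inclusive, so
5 × 40 kb = 200 kb qualifies), else at least 3 bins for unitless
matrices — and is a boundary otherwise.

`quality(i) = intra(i) − inter(i, j)`: `intra(i)` averages the upper
triangle of the TAD's diagonal block with self-contact cells excluded by
default (they are dominated by proximity artefacts and would inflate
every intra term equally; a flag restores them), and `inter(i, j)`
averages the full rectangle between TAD i's rows and the adjacent TAD j's
columns, skipping any boundary/gap segments in between. Interior TADs
average their two neighbour rectangles, terminal TADs use their single
neighbour, and a lone TAD (no neighbour at all) takes `inter = 0`, i.e.
its quality is its intra mean. The overall quality of a TAD set is the
mean per-TAD quality (−inf for a set with no TADs), and the window search
maximises it.

### Iterative refinement

A first pass over a real chromosome yields coarse clusters and large,
weakly cohesive TADs. Rounds 2..R (default 3) rank clusters by member
count, select the top 30% or 50% (default 50%) for re-clustering — capped
so at least half the clusters survive unsplit, with size ties resolved
toward the lower cluster id — and split each selected cluster with
`K = round(sqrt(size/2))` on its members' *original global* feature
vectors (no per-submatrix recomputation step is defined for the
procedure). Clusters of fewer than 4 members are left alone (their K
would fall below 2); sub-cluster labels are globally unique. Mean TAD
size shrinks from round to round on nested-domain data; all rounds are
returned and the CLI highlights the round with the best overall quality,
which is typically the second.

### Evaluation utilities

Two TAD sets are compared per TAD of method A: case A — some B-TAD
matches both boundaries within a tolerance (default 0 bins, i.e. exact;
±1 bin is common practice and configurable); case B — at least two B-TADs
are fully contained (one contained sub-TAD is deliberately *not* enough
and falls through to C); case C — some overlap without match or
containment; otherwise no overlap. The one-sided case (a region called
only by B) is obtained by swapping the arguments. The consistency
percentage is `100 · #(A or B) / #TADs of A`. Border enrichment counts
peak midpoints per offset bin in a ±window (default ±1 bin) around every
TAD start/end and averages over borders; midpoints make the count robust
to peak-width heterogeneity across marks.

## Synthetic data

`generate_block_matrix` plants domains as diagonal blocks: cell means are
`intra_mean` (default 10) inside a domain and `inter_mean` (default 2)
elsewhere, optionally damped by `(1 + |i − j|)^(−decay)`, perturbed with
Gaussian noise (default sd 1; Poisson available for count realism),
symmetrized by averaging, clipped at zero, and zeroed at gap bins. The
default 30-bin benchmark plants five domains of 8, 6, 6, 5 and 5 bins
(1-based ranges (1,8), (9,14), (15,20), (21,25), (26,30)), stored
internally 0-based. `generate_nested_matrix` adds a second level
(sub-domain mean > outer mean > background) for exercising the iterative
refinement; `generate_boundary_peaks` plants a fixed number of peaks in
every border bin over Poisson background.

What the generator does *not* emulate: read-count overdispersion,
distance-decay of real polymer contacts beyond a single power law,
translocations, copy-number effects, and compartment-scale (A/B) signal.
Passing tests on these fixtures show the machinery is correct — block
structure in, planted boundaries out — not that the caller is competitive
on real chromosomes.

## Problem sizes and numerical choices

The test suite and the acceptance script run on the 30-bin benchmark
(20-seed ensembles where a rate is measured) and one 500-bin matrix for
the scale check; these sizes keep the full suite in seconds while still
exercising every code path. Ties in K selection and elbow detection break
toward the smaller K; quality comparisons use a 1e-12 guard so
floating-point noise cannot flip a tie; brute-force oracle equivalence is
asserted at 1e-9.

## Known limitations

* The quality score is scale-dependent (a difference of means), so TAD
  sets from differently normalized matrices are not directly comparable.
* Under noise the per-K quality curve is nearly flat past the true K, and
  the window search may prefer a slightly finer segmentation than the
  planted truth; the elbow policy is more stable on small matrices.
* No nested/overlapping domain output: each round yields a flat tiling.
* Boundary significance is not tested statistically; enrichment profiles
  are descriptive.
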