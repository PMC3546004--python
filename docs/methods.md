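# Methods

This note documents the models and procedures implemented in
`chromalign`, the parameters that matter, the numerical conventions, and
the choices made where the design was genuinely open.

## Similarity model

Peaks and scans are binned mass spectra over an inclusive integer
nominal-mass range (default 50–550 Da, 501 bins). Binning rounds each
m/z half-up ("arithmetic rounding", the convention of chromatography
software; banker's rounding would make results platform- and
library-sensitive), sums intensities falling into the same bin and
discards out-of-range readings, so total in-range intensity is
conserved. Per-scan unit-length normalization removes linear intensity
scaling between runs; masking of derivatization masses (73 and 147 Da
for TMS reagents) removes near-ubiquitous background fragments that
would otherwise dominate every similarity.

The pairwise similarity between peaks p and q is
`f(p,q) = s(i_p, i_q) · exp(−(t_p−t_q)²/(2D²))`. The Gaussian factor is
1 at equal retention times and decays monotonically; it encodes the
assumption that elution order is locally preserved and that RT
deviations between runs stay within a few multiples of `D` (seconds).
Five spectral kernels are supported: cosine, dot product, negative
Euclidean distance, Pearson and Spearman correlation. Degenerate inputs
are defined to yield similarity 0 — all-zero vectors for cosine,
constant vectors for the correlations — because a flat spectrum carries
no identification evidence and 0 keeps NaNs out of argmax computations.

The threshold `T ∈ [0,1]` applies to the *penalty*, not to `f`: if
`exp(−Δt²/2D²) < T`, the spectral kernel is never evaluated and the pair
is pruned (reported via a counter). This is a pure speed device; with
`T = 0` the thresholded and unthresholded paths return identical values
(property-tested). In the DTW recursion, where every admissible cell
needs a value, pruned cells contribute similarity 0 instead of a
sentinel — the spectral term is still skipped, preserving the speedup
semantics.

## Peak-clique multiple alignment

For K chromatograms, only inter-chromatogram peak pairs are compared
(no self-similarities). Each peak keeps at most one best hit per foreign
chromatogram (argmax of `f`); mutual best hits (BBHs) form an unweighted
K-partite graph with maximum degree K−1, on which maximal cliques are
found greedily.

Conventions the underlying theory leaves open:

* **Best-hit tie-breaking.** Equal similarities resolve by smaller
  |Δrt|, then lower peak index — deterministic and favoring temporal
  proximity.
* **Merge order.** BBH edges are processed in descending similarity
  (ties by smaller |Δrt|, then lexicographic peak reference): strongest
  evidence first makes conflict resolution reproducible and lets
  high-confidence groups form before ambiguous ones.
* **Failed merges.** A merge happens only if the union of the two
  cliques stays complete (all pairs BBHs) with at most one peak per
  chromatogram. Otherwise committed cliques are left untouched — a peak
  already in a clique is never reassigned — and a lone peak that fails
  to join stays free to seed a later clique. With this policy every
  reported clique is complete by construction and *maximal with respect
  to unassigned peaks*: if an unassigned peak u were compatible with a
  final clique C, the BBH edge between u and any member m was processed
  at some point; at that time m's clique was a subset of C (cliques only
  grow), so u — compatible with all of C — would have joined or seeded a
  clique with m, contradicting u ending unassigned. The exhaustive
  oracle tests verify both properties on random instances.
* **Invalidated hits.** Once a BBH is fixed, the partners' remaining
  hits toward each other's chromatograms are dead by construction
  (argmaxes are precomputed); no finite "minimum similarity" floor is
  needed, which keeps invalidated entries from ever winning later.

Cliques with fewer than `MCS` members (2 ≤ MCS ≤ K) are discarded; rows
are ordered by the median RT of their members, with explicit absent
markers for uncovered chromatograms. Raising MCS monotonically shrinks
the table and trades recall for precision.

## Partitioned dynamic time warping

The DTW recursion maximizes summed similarity along a monotone,
continuous path from (1,1) to (M,N), with step weights `w_match`,
`w_comp`, `w_exp` (> 0). The default `w_match = 2.25` exceeds
`w_comp + w_exp = 2`, so in regions of uniform similarity the diagonal
strictly dominates a compression-expansion staircase — the standard
remedy for overadaptation when maximizing a similarity rather than
minimizing a distance. Row 0 and column 0 are −∞ except the origin,
forcing the global alignment of the first scans.

**Constraint layout.** Admissible cells are described per row as a
single column interval with nondecreasing bounds. The layout is built
from (a) inter-anchor partition rectangles, (b) a Sakoe-Chiba band —
global (one corridor of width `ceil(w·max(M,N))` cells around the full
diagonal) or local (one corridor per partition, width proportional to
the partition's larger side) — and (c) anchor boxes: rows within radius
`r` of an anchor admit exactly the `±r` box around the anchor cell, so
`r = 0` pins the path to the anchor. Band windows are shifted, not
truncated, at matrix edges, so a band width of 1.0 degenerates to the
full matrix. Anchors are first reduced to a monotone chain: sorted by
the first coordinate, a longest strictly-increasing subsequence on the
second coordinate removes order inversions with the fewest deletions
(ties resolve to the standard tails reconstruction), and anchors
directly adjacent to their predecessor in both coordinates are dropped
as redundant. After intersecting all constraints, each row's interval is
widened minimally so consecutive rows overlap or abut diagonally — the
raw intersection can strand the recursion — and construction fails
loudly if (0,0) and (M,N) still cannot be connected.

**Storage.** Admissible cells are stored row-compressed (one linear
array plus per-row offset and length); reads outside the layout return a
configurable default (−∞ for scores), writes outside are no-ops. With a
local band of width fraction `w` the stored-cell count is bounded by
`ceil(w·max(M,N))·(max(M,N)+1)` plus anchor-radius overhead, which
operationalizes the linear-in-bandwidth complexity of the partitioned
algorithm.

**Numerical conventions.** Traceback prefers match over compression
over expansion on exact ties, keeping paths deterministic and
diagonal-leaning. The final score `Q(M,N)` is *weight-corrected* by
dividing by the sum of step weights along the optimal path; this reduces
to a per-step average similarity and makes scores comparable across
series lengths. (Normalizing by M+N or by path length are defensible
alternatives; path-weight normalization was chosen because it is exact
for the path actually taken.) Local similarity maxima along the path —
aligned, highly similar spectra — are reported with a plateau-first
rule, endpoints qualifying with a single neighbor.

**Center-star assembly.** All K(K−1)/2 pairwise weight-corrected scores
are computed first (when `w_comp = w_exp` the score is symmetric and a
stored path can be reused in the reverse orientation; otherwise the
center's paths are recomputed in the correct orientation). The
chromatogram with the highest summed score to all others becomes the
reference, ties resolving to the lowest index. The output table has one
row per reference scan and no missing entries; when several scans of
another run map to one reference scan, the cell records the scan with
maximal similarity to the reference scan and the full mapped range is
kept in an auxiliary per-row structure.

## Evaluation

Ground truth is a table of peak groups marking, per chromatogram,
presence (a scan index) or absence. Truth-to-prediction row
correspondence is not dictated by the counting rules themselves, so it
is defined here as greedy maximum overlap: rows pair by the number of
chromatograms whose entries agree within a scan tolerance, ties by
smaller median-RT gap, each predicted row used once. Within a pair,
present/present within tolerance counts TP (outside tolerance: FP and
FN), absent/absent TN, absent-in-truth/present FP,
present-in-truth/absent FN; unmatched truth rows contribute their
present entries to FN. Predicted rows matching no truth group are
reported as *unassignable* rather than as FP — the reference makes no
statement about them, and for dense profile alignments (one row per
scan) they are the rule, not the exception. Profile mode reports TP/FP
only, since a dense alignment has no absences from which to count TN or
FN. Precision and recall with zero denominators are reported as
undefined (not 0); F1 is 0 by convention when precision = recall = 0.

## Synthetic data generator

The generator emulates the features of a real GC-MS batch that the
aligners are sensitive to: shared compounds with distinct sparse EI
spectra (5–30 fragment bins, pairwise cosine < 0.95 by rejection),
reference RTs on a jittered grid guaranteeing separation, per-run
smooth monotone RT warps (PCHIP through random knot offsets pinned to
zero at the run ends, so the shift never exceeds the configured
amplitude and time never folds back; chromatogram 0 is the undistorted
reference), lognormal between-run intensity variation, Gaussian spectral
noise truncated at zero, Bernoulli peak dropout, Gaussian elution
profiles over an even scan grid, and a flat baseline. The defaults — 5
runs, 600 scans over 600 s, 50 groups, 10 s warp amplitude, 30%
intensity CV, no dropout — are a desk-scale rendition of the published
benchmark batches (thousands of scans, hundreds of peaks, RT deviations
up to tens of seconds); sizes were scaled down so the whole study runs
in seconds while keeping scan density, peak spacing and warp magnitude
in realistic proportion.

What the generator does *not* model — co-elution and deconvolution
errors, mass-dependent detector response, spectral skew across a peak,
baseline drift, column bleed — bounds what passing tests show: recovery
on this data demonstrates correctness of the matching, clique, warping
and scoring machinery under realistic drift and noise, not robustness to
every artifact of real instruments. All randomness flows from a single
seed through fixed-offset substreams, so datasets are bit-reproducible.

## Known limitations

* The greedy clique merger is order-dependent by design; which of two
  equally supported small cliques survives a conflict depends on the
  similarity ranking of their edges.
* Evaluation row-pairing is greedy, not an optimal assignment; on
  pathological overlap structures the pairing can differ from the
  exhaustive maximum (tests use instances with unique best partners).
* The center-star alignment inherits the usual heuristic caveat: peaks
  absent from the reference can degrade the multiple alignment, and no
  global optimality bound is claimed.
* High-resolution (non-integer-bin) spectra, MS/MS similarity,
  free-end-gap DTW and the Itakura parallelogram constraint are out of
  scope.
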