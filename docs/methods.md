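# Methods

## Graphical encoding

A sequence of length *l* maps to *l* + 1 planar points by cumulative
summation of per-residue step vectors from the origin.  Every step advances
x by exactly 1, so the x-coordinates are 0, 1, …, *l* and the curve is a
function graph.  The four DNA steps (T (1, 2/3), A (1, 1/3), C (1, −1/3),
G (1, −2/3)) have distinct y-components, so the DNA encoding is invertible:
no information is lost, and the test suite exercises the inverse.

Protein y-steps are derived from a 20-value hydrophobicity scale by a
rank-uniform construction: the *P* residues with positive scale values
receive y = rank/*P* in ascending scale order (most hydrophobic → +1), the
*Q* non-positive ones y = −rank/*Q* in descending order (most hydrophilic →
−1).  The default scale is Fauchere–Pliska (1983) octanol/water π values;
any tie-free 20-value scale, or a fully explicit step table, can be
substituted.  Ambiguity codes are not assigned steps: the reader either
rejects them (default) or drops them on request, because silently encoding
them would change every downstream distance.  RNA `U` is transliterated to
`T` before validation.

## Minimum 1D Hausdorff distance under translation

`f(t) = h(A + t, B)` is piecewise linear with slopes ±1.  Its minimum is
therefore attained either where `f` reaches 0 (`t = b_j − a_i`) or where a
rising branch crosses a falling one (`t = (b_j + b_k − a_i − a_l)/2`).
Enumerating all those candidates and evaluating `f` at each is the
brute-force oracle (`oracle_min_hausdorff_1d`), quadratic in *mn* and
guarded to ≤ 50 points per set.

The production minimiser runs a bisection on the distance value δ with an
exact feasibility test: a shift achieving `f(t) ≤ δ` exists iff the
admissible window `[max(b₁−a₁, bₙ−aₘ) − δ, min(b₁−a₁, bₙ−aₘ) + δ]` is not
fully covered by the open "forbidden" intervals produced by gaps wider
than 2δ in either set (a gap of B wider than 2δ strands any `a_i + t`
placed mid-gap, and symmetrically).  Gaps are indexed once per pair, sorted
by width, so each probe selects the active gaps with one binary search and
sweeps the merged intervals vectorised.  The bracket starts at the provable
bounds `lb = |diam A − diam B|/2` and `ub = h` at the midrange-aligning
shift (tightened by two further edge-aligning shifts), and closes to an
absolute width of `1e−12 × scale`; the reported distance is the exactly
evaluated `h(A + t*, B)` at the witness shift, so the result invariant
`distance = h(A + t_star, B)` holds to round-off and the minimiser matches
the oracle far below the 1e−9 contract.  Among near-optimal shifts the
leftmost witness is reported, making `t_star` the smallest optimal shift up
to the bisection resolution.  A run costs `O((m + n + K) log(range/tol))`
with *K* the number of active gap–point pairs; this is not the
`O((m+n) log(m+n))` parametric-search bound of the literature, but it is
exact, branch-free to verify, and fast enough that the full pipeline is
dominated by the number of H¹ calls rather than their individual cost.

## Rotation sets and the Yau-Hausdorff distance

Each point set receives *alignment angles* — for pivots a₁, a₂, a₃ (the
first three points in curve order) and every later partner, the angle
`−atan2(Δy, Δx)` that makes the pivot→partner segment parallel to the
x-axis — plus, by default, each angle's antipode (the two projections are
mirror images, which H¹ under translation does not equate for ≥ 3 points),
plus `n_random` (default 1000) uniform random angles.  An `all_pairs` pivot
mode is available for accuracy studies.  Random draws are seeded from the
user seed combined with a translation-invariant content hash of the point
set (coordinates normalised to the lexicographically smallest point and
rounded to 9 decimals), so equal or merely translated sets always receive
identical rotation sets.  This makes `D(A, A)` exactly zero and keeps `D`
translation-invariant even in random-angle mode; whether random rotations
should be drawn per point set or per comparison is not fixed by the
method's description, and per-set draws are the reproducible choice.

`D` is the max–min of H¹ between x-projections over the two rotation sets,
taken in both directions.  Evaluating it naively costs |M|·|N| full H¹
minimisations.  The implementation preserves the result while skipping
most of that work:

* projections for all angles of a set are computed and column-sorted once
  (`PreparedPointSet`), and reused across pairwise comparisons;
* `|diam_θ − diam_φ| / 2` is a provable lower bound on each pair's H¹;
  the outer loop descends by the best such bound so the running maximum
  rises early;
* one Hausdorff evaluation at the midrange-aligning shift gives each outer
  candidate a cheap upper bound on its inner minimum; candidates whose
  bound cannot exceed the running maximum are discarded outright;
* inside a surviving candidate, each pair's bisection aborts as soon as its
  lower bracket proves it cannot lower the current inner minimum (`floor`),
  or — with pruning on — as soon as its upper bracket proves the whole
  candidate irrelevant (`cutoff`).

Pruning never changes which value is the maximum in exact arithmetic; in
floating point the discard comparisons can flip at the last unit of
precision, so pruned and unpruned runs are asserted to agree to 1e−12
(observed differences are a few 1e−16), not bit-for-bit.  With pruning
disabled every pair is refined and the loops depend on nothing but the
rotation sets.

`hausdorff_2d` delegates to `scipy.spatial.distance.directed_hausdorff`.
The minimum 2D Hausdorff distance under rigid motion, which `D` lower
bounds, is provided only as a testing oracle: a grid search over `n_theta`
uniform rotations and an `n_t × n_t` translation grid spanning the
bounding-box offset range.  It upper-bounds the true value with a slack of
half a translation cell diagonal plus `Δθ × r_max`, and runs in single
precision (the grid resolution dwarfs float32 rounding; exact coincidences
still produce exact zeros).  Note the finite rotation sets make `D` itself
an approximation of its continuum definition: enlarging `M` can only raise
the outer maximum while enlarging `N` can only lower the inner minimum, so
no monotonicity across option settings is asserted — only determinism per
setting, and the lower-bound relation is checked empirically.

## Clustering

UPGMA merges the closest pair of clusters at height d/2 (so two leaves at
distance d are separated by a path of length d) and updates distances by
the member-count-weighted mean.  Average linkage is reducible, hence merge
heights are monotone and branch lengths nonnegative.  Determinism under
ties: the pair whose (smallest-leaf-label, smallest-leaf-label) tuple is
lexicographically least merges first, and children are ordered by smallest
leaf label, so the Newick output is a canonical form.  Tree topology
comparison reduces both trees to their leaf bipartitions (Robinson–Foulds
distance zero ⇔ equal); dendropy and scipy's average linkage serve as
independent cross-checks in the test suite, not as the implementation.

The natural graph presents the same matrix as levelled nearest-neighbour
clusters: at level 1 every item points to its closest item (ties to the
lexicographically smallest label; mutual pairs collapse to one
bidirectional edge) and weakly connected components become clusters; at
level k each cluster points to its closest cluster under single-linkage
distance, with edge length equal to that distance (proportionality
constant 1).  Iteration stops at a single component or `max_level`
(default 3).

## Synthetic data and experiments

The generator produces i.i.d. uniform sequences, point-substitution
mutants, contiguous-deletion series and sequence families, all
deterministic per seed.

*Families.*  Because `D` is invariant under rotation and translation, two
same-length random walks are often surprisingly alignable, and composition
bias makes curves nearly straight — hence nearly congruent under rotation.
Robust between-family separation therefore needs founders that differ in
shape extent: family *f* has length `length + length_step · f(f+1)/2`
(successive gaps grow, so no two inter-family distances nearly tie) with
independent random content, and members differ from their founder by
`n_substitutions` point substitutions (default 1).  The stability analyses
use 3 families × 2 members, base length 30, step 25 — the realized
separation (between-family minimum exceeding the within-family maximum
plus the largest perturbation-induced matrix change) is asserted before
topology stability is, so a failure distinguishes "families not separated"
from "method not stable".  This generator emulates length and substitution
divergence only: no indel mosaics, no base-composition skew, no shared
phylogenetic signal — passing tests show metric stability under noise, not
phylogenetic accuracy on real families.

*Perturbation.*  "Within 10% of the y-coordinates" is read
multiplicatively: each curve point's y is scaled by `1 + u`, `u` uniform in
[−fraction, +fraction], independently per point, applied to the
accumulated curve (not the steps); an additive mode is provided behind a
flag since the phrasing admits both readings.

*Deletion scan.*  Deletion lengths 1..`max_deletion` are spread evenly over
`n_mutants` (each length exactly once when the counts match, e.g. 150
mutants of a 350 bp base give mutant lengths 349..200), each deletion at a
seeded random start.  The reported quantity is the Pearson correlation
between deletion length and distance; only its sign is asserted, the slope
is not.

*Runtime profile.*  Wall-clock and H¹ call counts per curve length, with
pruning's call reduction visible; purely observational.

## Problem sizes and tolerances

The test suite checks oracle agreement on 1000 random 1D instances (≤ 20
points, mixed integer/float) at 1e−9; metric axioms on 200 curve triples
(lengths 5–30, alignment-only angles) with triangle slack 1e−6; rigid
motions at 1e−9 over 100 transforms; the lower bound on 100 pairs of 4–10
point sets against the 720 × 61² grid with its resolution slack, using 100
random rotations per set; and the full-scale deletion scan (350 bp, 150
mutants, 50 random rotations) plus 5 stability repeats.  The acceptance
script uses the same machinery at 300 oracle instances, 100 triples, 50
motions and 20 lower-bound pairs on a 360 × 41² grid.  These sizes keep a
complete run in minutes on one core while every property is exercised at
full strength; the deletion scan and stability runs are at the scale the
experiments were designed for.

## Known limitations

* Pairwise cost grows quadratically in sequence length through the
  rotation-set product; ~10⁴-residue sequences are feasible, millions are
  not.  `PreparedPointSet` stores one sorted projection per angle
  (O(n·|M|) memory, ~6 MB per 350 bp curve), so matrices over many long
  sequences are memory-hungry.
* `D` with finite rotation sets is an approximation of the continuum
  max–min; alignment-only mode is exactly reproducible and rigid-motion
  invariant, while random-angle mode trades a denser rotation cover for
  content-hash-seeded (still deterministic) draws.
* The published protein experiments depend on a specific 20-value table
  that is not reproduced here; the rank-uniform Fauchere–Pliska default is
  a faithful construction of the described procedure, but numeric results
  on protein data will differ from any source using a different table.
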