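# Methods

## The space

A point of wald space is an equivalence class of forests on leaves
`1..N`: unlabelled vertices have degree ≥ 3, every edge carries a length
`l ∈ [0, ∞]` or equivalently a weight `λ = 1 − exp(−l) ∈ [0, 1]`, pendant
edges of raw input trees must have `l > 0`, and every same-component leaf
pair must be separated by at least one positive-weight edge (no
coincident leaves — this is what keeps all induced distributions
non-degenerate).  Two reduction rules generate the equivalence:
contracting internal weight-0 edges (so an unresolved tree is the common
boundary of the orthants of its resolutions), and deleting weight-1
edges, which disconnects a component; an unlabelled degree-2 vertex left
behind is suppressed with the two incident lengths added (weights combine
as `a + b − ab`).  `canonicalize` applies both rules to exhaustion; the
result is unique because neither rule can re-create a removable edge, and
two forests are equivalent iff their canonical forms have identical
component partitions and split-to-length maps (lengths compared at
absolute tolerance 1e−12).  This combinatorial test is validated against
the model-based criterion: equivalent forests induce identical character
distributions, and only they do.

Coordinates on a maximal orthant are the `2N − 3` edge lengths (or
weights) of a fully resolved tree, ordered deterministically: pendant
edges by leaf label, then internal splits lexicographically by their
smaller side.  All vectors and tensors in the package use this order.

## Models and metrics

**Two-state model.** A symmetric binary Markov chain in its Bern(1/2)
stationary state runs over the forest; an edge of length `l` preserves
the state with probability `(1 + e^(−l))/2`.  The pmf over the `2^N`
characters is computed by post-order pruning per component (guarded at
N ≤ 16).  Because each edge's transition matrix enters the product
exactly once, the pmf is *multilinear* in the quantities `e^(−l_e)`;
exact first and second derivatives in the edge lengths are therefore
obtained by re-running the pruning with one or two edges' transition
matrices replaced by their derivatives — no finite differences anywhere
in the metric pipeline.  The Fisher matrix, its derivative and the
Christoffel symbols follow from the standard formulas; the quadratic form
of the metric reproduces twice the Kullback–Leibler divergence of nearby
trees to third order (and, after the `2/f''(1)` normalization, any
f-divergence — tested with `t log t` and `−log t`).

**Gaussian model.** A stationary OU process with unit stationary variance
gives a zero-mean normal with covariance `S = (e^(−l_uv))`, zeros across
components.  With split matrices `σ^e` (the 0/1 indicators of which leaf
pairs an edge separates), `∂_i S = −(σ^i ∘ S)` and
`∂_k ∂_i S = σ^i ∘ σ^k ∘ S`, so the pullback of the affine-invariant SPD
metric and its first *and second* derivatives are closed-form; Christoffel
symbols and the full Riemann tensor are assembled analytically and
verified against finite differences and the tensor symmetries.  Sectional
curvatures of coordinate planes at random 5-leaf trees take both signs,
so no global curvature bound of the BHV kind is available.  The two
metrics are *not* proportional — their Christoffel symbols differ
markedly at short edge lengths and converge as lengths grow — but their
geodesic loci agree to a few percent of path length, which is why the
cheaper Gaussian model is the default everywhere.

## Geodesic shooting

Classical RK4 on the geodesic ODE with analytic Christoffel symbols,
default step 5e−3 in (unit-speed) time.  Boundary handling follows the
stratification: an internal coordinate reaching 0 stops integration (the
event time bisected to 1e−10); a pendant coordinate reaching 0 is clamped
to 0 and its velocity zeroed, and integration continues — the velocity
treatment at the clamp is a choice, recorded in the output flags.
Integration runs in either length or weight coordinates; the weight-chart
Christoffels are assembled from the weight-chart metric and its exact
derivative rather than by transforming the length-chart symbols, because
near the boundary at infinity the length-chart metric underflows while
the weight-chart one stays well-conditioned.  On the `λ = 1` face itself
the orthant chart genuinely degenerates (coordinates inside a freshly
disconnected component no longer affect the distribution), so arrival is
declared at `λ ≥ 1 − 1e−5`; the finite-time-arrival result is insensitive
to this margin since the remaining distance is of the same order.

## Projection

Squared ambient distance to a fixed SPD matrix has the analytic gradient
given in `wald_projection`; descent uses BB1 steps `α = sᵀs/sᵀy`
safeguarded to `[1e−8, 1e2]`, halving backtracks on objective increase,
and two extra safeguards that proved necessary: a geometric step growth
when the BB curvature signal is at roundoff level (flat objectives deep in
saturation), and a stagnation stop after 5 consecutive relative
improvements below 1e−14.  Convergence is declared at gradient ∞-norm
below 1e−8 or 5000 iterations; lengths are capped at 50 (weights within
2e−22 of 1) and negative pendant proposals clamped to 1e−10.  The
orthant-constrained variant halts when the iterate is pinned against an
internal-length-0 boundary and the gradient still points outward.  The
crossing variant re-reads a negative internal proposal in the two
NNI-neighbour orthants with absolute values as lengths and continues from
the closer — but first compares against staying clamped on the boundary,
crossing only on strict improvement; without this the iteration
ping-pongs forever whenever the optimum lies on the shared stratum (which
is exactly the situation in the star-stratum experiment).  Equidistant
neighbour ties are broken toward the lexicographically smaller topology
and logged.  The global variant restarts the orthant-constrained descent
once per maximal orthant (all `(2N−5)!!`, guarded at N ≤ 6) from lengths
0.5 and returns the best run.

## Approximate boundary-value geodesics

The recursive scheme walks from the start forest to the fixed destination
covariance, at iteration `i` stepping a proportion `1/(k−i+1)` along the
current ambient geodesic and projecting with the crossing variant,
initialized from the previous forest.  The symmetrized scheme grows both
ends simultaneously with proportions `1/(k−i+1)` and `1 − 1/(k−i+1)`;
swapping the endpoints reverses the ambient geodesics exactly, so the
output sequence is exactly reversed.  The two half-sequences are joined
as `[G_0..G_{k−1}, H_{k−1}..H_0]` and the seam segment is included in the
length sum (at the final iteration both proportions are 1/2, so the seam
segment is zero); path length is the sum of ambient `d_cov` over
consecutive points, which always dominates the single ambient chord and
*increases* toward the underlying arc length as `k` grows (finer chords
under-estimate less).  Default `k = 64`; the experiments below use
`k = 16` per curve point, which resolves the qualitative shape at a
fraction of the cost.

On the standard five-leaf instances (all pendant lengths 0.1, internal
lengths 0.3 and 0.2) the symmetrized path between the one-NNI pair is
shorter than both recursive orientations once both are measured at
converged resolution.  On the two-NNI pair, however, our recursive paths
are consistently 0.2–0.7 % *shorter* than the symmetrized ones — checked
over `k` up to 64, several internal-length settings, and at matched
resolution by projected-midpoint refinement.  Both constructions are
heuristics without optimality guarantees and the gap is small; we report
the lengths as computed rather than forcing an ordering.

**Star-stratum experiment.** For `λ0 ∈ {0.1, 0.5, 0.9, 0.95}` the
symmetrized scheme approximates the intrinsic distance from the resolved
4-leaf tree with all weights `λ0` to the star tree with all weights `λ`,
over a grid of `λ`.  The minimizing `λ` always exceeds `λ0`, the minimum
decreases as `λ0 → 1`, and the curve blows up as `λ → 0` (the limiting
covariance matrix is rank-deficient, so `λ = 0` is rejected).  Star-tree
endpoints are unresolved; gradient descent is seeded from a resolved
representative with a 1e−8 internal edge.

## Synthetic data

`simulate_characters` draws i.i.d. binary characters by rooting each
component arbitrarily, sampling the root from Bern(1/2) and flipping
along edges — the exact finite-dimensional law of the substitution
process, so simulation tests calibrate against the analytic pmf and
covariance (chi-square goodness of fit at α = 0.01, 1e5 sites).
`random_tree` draws topologies uniformly over the `(2N−5)!!` resolved
topologies by sequential random leaf insertion and lengths i.i.d.
exponential with mean 0.5 — a scale chosen so that typical trees sit in
the informative regime between the zero-length and saturation boundaries.
These generators emulate the model exactly; what they do not emulate is
real sequence data (finite alignments, rate heterogeneity, 4-letter
alphabets), so passing tests validate the geometry implementation, not
model adequacy for data.

## Sizes, tolerances, limitations

Exact character-distribution computations are exponential in N and
guarded at N ≤ 16; experiments run at N = 4–5 (the paper-scale setting
that permits visualization) with topology enumeration guarded at N ≤ 9
and global projection at N ≤ 6.  Matrix functions go through symmetric
eigendecompositions with a relative eigenvalue floor of 1e−12 below which
inputs are rejected, never regularized — rank deficiency signals a
degenerate forest.  Serialized Newick keeps 12 significant digits, so
round-trip equality holds at 1e−9, not machine precision.  Projection can
converge to local minima; the closest point in wald space to an ambient
matrix need not be unique (points equidistant from two orthants exist),
which is inherent to the space, not the algorithm.
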