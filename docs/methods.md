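# Methods

## The objective

All of `netkl` minimizes one functional. A weighted network is a symmetric
matrix of non-negative reals `a_ij` read as unnormalized probabilities of
the index pair (i, j); a representation is a second non-negative matrix
`b_ij` on the same index set. Their distinguishability is the relative
entropy

    D(A‖B) = Σ_{a_ij > 0} (a_ij / a_**) ln[ (a_ij / a_**) / (b_ij / b_**) ],

in nats, with `a_**` and `b_**` the totals of each matrix. D is invariant
under separate rescaling of A and B, non-negative, and zero only when the
normalized matrices coincide. Writing D = H(A, B) − S(A) with the
cross-entropy H(A, B) = −Σ (a_ij/a_**) ln(b_ij/b_**) shows that the
optimizer of B is linear in the entries of A at fixed total: representing
the mean of a noisy matrix ensemble is the same problem as representing
the whole ensemble, which is why layouts are robust to entry-level noise.

Two reference scales normalize D. The product state
`b⁰_ij = a_i* a_*j / a_**` is the best structureless representation and
satisfies `D(A‖B⁰) = I(A)`, the mutual information between rows and
columns; η = D/I(A) therefore runs from 1 (trivial) to 0 (perfect) and is
the package's default quality ratio. The alternative η_S = D/S(A) — the
extra description length relative to the optimal code length for the data
— is the scale on which the layout percentages in the README and the
acceptance report are quoted; both are available everywhere through
`norm="mutual" | "entropy"`.

### Diagonal conventions

Inputs that are simple graphs have structurally zero diagonals;
representations generally do not. The package resolves this edge case by
family, choosing in each case the convention under which the family's
exact identities hold:

* product states and block inflations keep their diagonal entries and
  count them in `b_**`. This is what makes `D(A‖B⁰) = I(A)`, the row-sum
  preservation of inflation, and `D = I(A) − I(M)` identities exact.
* Gaussian overlap matrices for zero-diagonal inputs exclude the
  self-overlap `b_ii` from `b_**`: a node is never compared with itself,
  and counting the self-mass would put a spurious floor
  `ln(b_**/(b_** − Σ b_ii))` under every layout's divergence (about a
  fifth of the overlap mass on realistic layouts — far above the
  attainable D). A consequence worth knowing: the coincident
  product-state initialization of a layout then starts at
  `D₀ = I(A) + ln(1 − Σ (a_i*/a_**)²)`, marginally below I(A) (3.6% below
  on the karate network); for inputs that carry their diagonal —
  incidence-derived matrices `A ~ HᵀH` and the reduced matrices of the
  hierarchical stages — the self-overlap is part of the representation,
  `b_**` includes it, and `D₀ = I(A)` is exact.

`0 · ln 0 := 0` throughout; all logarithms are natural.

## Gaussian layouts

Node i is the isotropic Gaussian with norm `h_i` (its integral), width
`σ_i` and position `x_i ∈ R^d`; the overlap integral gives the closed
form

    b_ij = h_i h_j [2π(σ_i² + σ_j²)]^(−d/2) exp(−‖x_i − x_j‖² / (2(σ_i² + σ_j²))).

`∂D/∂θ_k = Σ_j 2 (q_kj − p_kj) ∂ ln b_kj/∂θ_k` for any parameter of node
k (p = a/a_**, q = b/b_**): a pair under-represented relative to its edge
weight attracts, an over-represented one repels, and pairs with a_kj = 0
act only through the `b_**` normalization — pure repulsion — so B never
needs denser storage than A.

Optimization is coordinate-wise and monotone: pick the node with the
largest position-gradient norm, apply a Newton step on its own d×d
analytic Hessian (falling back to backtracking gradient descent whenever
the Hessian is not positive definite or the step fails to lower D), and
every N single-node picks run a full sweep that also updates each σ_k and
h_k by a one-dimensional Newton step in log-space (analytic first
derivative, finite-difference curvature, backtracked). Steps are accepted
only if D strictly decreases, so the trace is non-increasing by
construction. Convergence: max gradient norm < 1e-8, or relative D change
< 1e-9 over a sweep, or the iteration cap (100 node updates per node).

Defaults follow the protocol that produced the reference figures: norms
start pinned at `h_i ∝ a_i*` (`freeze_h=True`) and a fine-tuning phase
(`fine_tune=True`) releases widths and norms after the frozen phase
converges. The width floor is `σ ≥ 1e-6 ×` the coordinate spread, only a
numerical guard. Multi-restart searches derive every seed from one
user-visible `random_state` via `SeedSequence`.

Bookkeeping is incremental: moving one node touches one row/column of B,
so a move costs O(N). Two numerical hazards are handled explicitly.
First, log-overlaps are stored centered on their admissible maximum so
`exp` cannot underflow globally (only `ln b − ln b_**` matters). Second,
for zero-diagonal inputs the stored B has its diagonal zeroed outright —
self-overlaps of small-σ nodes can exceed the admissible mass by many
orders of magnitude, and subtracting a trace from a sum that large
cancels catastrophically. Running totals are resynchronized from scratch
whenever they decay far below their refresh scale, and periodically.

### One dimension: seriation

Gradient steps cannot change the order of nodes on a line — permutations
are separated by divergence barriers — so `n_components=1` adds two
combinatorial move classes after each converged continuous phase:
reinsertion (teleport one node into any inter-node gap, then re-optimize
it locally) and segment reversal (mirror a contiguous run of the current
order — the 2-opt move of seriation — screened with two quick sweeps).
Moves are accepted only on strict divergence decrease and the cycle
repeats until neither class improves. Each hierarchical restart is
polished independently, because the polish fixpoint depends on the basin
the restart lands in. The final ordering is read off the coordinates,
ties broken by input index, reflection canonicalized so the first node's
index precedes the last's.

The optional homogeneous-disc kernel (`disc_overlap`, d = 2) is provided
for comparison; being non-differentiable at tangency it is exercised by
coordinate search, not Newton steps, and unlike Gaussians it can reach
D = 0 on sparse graphs.

## Coarse-graining

A partition P with groups r of total degree `κ_r` replaces A by the
reduced matrix `m_rs = Σ_{i∈r, j∈s} a_ij` inflated back at fixed degrees,
`b_ij = a_i* a_j* m_{g(i)g(j)} / (κ_{g(i)} κ_{g(j)})` — the unique
degree-proportional, symmetric expansion with every row sum preserved
exactly. The divergence of this representation is the lost mutual
information, `D = I(A) − I(M)`, and both evaluation routes are
implemented and must agree to 1e-10. Fusing exactly proportional rows
costs nothing; fusing everything costs I(A). At fixed group count,
minimizing D is identical to maximizing the Karrer–Newman
degree-corrected block-model kernel `Σ_rs m_rs ln(m_rs/(κ_r κ_s))`
through the identity `D = I(A) − (score/a_** + ln a_**)`.

Greedy agglomeration merges, at every step, the pair of groups with the
smallest divergence increase ΔD, computed locally in O(G) from the two
rows and the 2×2 block. Exact mode (default up to 200 nodes) re-evaluates
all pairs each step with a vectorized O(G³) pass; ties break to the
lexicographically smallest id pair, making dendrograms deterministic.
For larger networks a lazily invalidated priority queue over
graph-distance ≤ 2 candidate pairs approaches quadratic time; because a
third-party merge also perturbs the delta of an untouched pair (through
the shared columns), heap entries older than the last merge are
recomputed on pop rather than trusted — the structure stays exact-greedy
over its candidate set. Batch mode fuses the best ⌈fraction·G⌉ disjoint
pairs per round, recording each merge's actual delta at merge time so
heights stay exact and monotone. Heights are cumulative D; the last
equals I(A) to 1e-9.

Cuts undo the last G − 1 merges via union-find; `refine_partition` runs
Kernighan–Lin-style single-node reassignment sweeps on the cut, accepting
only divergence decreases and never emptying a group. Dendrograms export
as scipy linkage arrays, merge-table TSV, and Newick with branch lengths
equal to height differences.

## Hierarchical layout

The dendrogram is replayed in reverse: one Gaussian holds the whole
network, fusion steps are undone (`expand_batch` per stage, default 1 up
to 100 nodes, 5% beyond), and between expansions the current reduced
matrix is laid out with group norms pinned to `κ_r/a_**`. An undone
merge places the two children at `x_parent ± jitter·σ_parent·u` (seeded
unit vector u, jitter default 0.1 — at 0 the expansion is exactly
divergence-neutral but also a stationary point the optimizer cannot
leave), with widths inherited and the norm split by degree. At a scale
with G groups the full-size representation induced by the group
Gaussians satisfies `D(A‖B_full) = D_coarse(G) + D(M_G‖B_G)`, so the
coarse-graining divergence is a hard lower bound for the layout at every
scale; the implementation asserts it at each stage. Widths are optimized
at all scales; norms stay frozen throughout unless `fine_tune=True`
releases σ and h in the final full-resolution stage. Per-stage
optimization is capped at 60 node updates per group by default
(`optimize_iters`).

## Synthetic data

`PlantedModel` is the degree-corrected planted-partition generator the
coarse-grainer is matched to: expected weight
`a_ij = θ_i θ_j ω_{g(i)g(j)}` with per-group-normalized propensities θ
and symmetric block affinities ω; `mode="poisson"` draws symmetric
Poisson counts around it. With self-loops included the expected matrix
has exactly proportional rows within blocks, so the true partition loses
no information — the generator realizes the model family for which the
agglomerator's identities are exact. The canonical benchmark
(`PlantedModel.two_block`) uses two groups of 20, affinity contrast 8:1,
and a density giving mean weighted degree ≈ 34 — comparable to the
karate fixture's weighted degrees and deep enough in the exact-recovery
regime that failures indicate algorithmic, not statistical, error: at
mean degree ~9 the Poisson fluctuations of single-node degrees already
make occasional misassignments information-theoretically unavoidable.
`noisy_ensemble` produces Gamma-multiplicative replicates rescaled to a
fixed total, the regime in which the cross-entropy linearity argument
applies verbatim.

What the generator does not emulate: degree heterogeneity beyond θ,
weight dependence between pairs, sparsity patterns of real interaction
networks, or missing-data structure. Passing the recovery criterion
therefore demonstrates correctness of the objective and its optimizer on
the matched model family, not performance on adversarial real data; the
karate figures are the real-data check.

## Numerical choices and limitations

* All randomness flows from a single seed through `SeedSequence`; derived
  seeds stay below 2³¹. Equal seeds give identical results bit-for-bit.
* The layout objective is non-convex; multi-restart best-of selection is
  the only global device in d ≥ 2. Reported qualities are upper bounds on
  the attainable minimum (broader basin-hopping searches find d = 2
  divergences another ~50% lower than the default protocol's).
* Exact greedy agglomeration is O(N⁴)-ish in the worst case and intended
  for N up to a few hundred; the candidate-restricted heap mode covers
  larger inputs at the cost of exactness guarantees outside its candidate
  set.
* Layouts require symmetric inputs. Hypergraph/bipartite data enter via
  the incidence route (orderings for rows and columns come from HHᵀ and
  HᵀH respectively); directed layouts are out of scope.
* The divergence of a Gaussian layout is always positive for graphs with
  any structure: full-support distributions cannot represent hard zeros.
  Finite-support shapes (the disc kernel) can reach zero but lose
  differentiability.
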