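# Methods

This note records the model, the numerical and design choices, and what the
synthetic generators do and do not emulate.

## Model and procedure

The dynamics are linear time-invariant on the binary adjacency of a simple
directed graph: `x'(n) = A x(n) − B u(n)`, `y(n) = C x(n)`, with one driver
(`B` a canonical basis vector) and `S` targets (`C` a row selector).  Edge
signs (activation/inhibition) are stored but never enter `A`: the
controllability question is structural, and the binary convention also
underlies the total-degree statistic `k_i = Σ_j A_ij + Σ_j A_ji` (a
reciprocal pair contributes 2 to each endpoint; a self-loop contributes 2
to its node).  The control signal itself is never designed; only
controllability is assessed.

The target controllability matrix `Q_T = [CB, CAB, …, CA^(N−1)B]` has walk
counts as entries: `(Q_T)_{i,j}` = number of directed walks of length `j−1`
from the driver to target `i`.  Its rank counts controllable targets.  The
package computes `Q_T` by iterated integer matrix–vector products over the
predecessor lists, keeping exact arbitrary-precision integers throughout —
counts grow like `λ^j` with the subgraph's spectral radius `λ`, and silent
float overflow is precisely the failure mode under study.

**Subgraph reduction.**  Every node on no driver→target walk is removed
before building `Q_T`: the retained set is (forward-reachable from the
driver) ∩ (backward-reachable from the target set), plus the driver.  Walks
from the driver to a target never leave this set, so the reduced matrix is
a column truncation of the full one and, by Cayley–Hamilton on the reduced
dynamics, has the same exact rank.  Numerically it is far better behaved.

**Stepwise selection.**  Targets are added tentatively in ranking order;
after each addition the subgraph is rebuilt from scratch (fidelity over
speed — the rebuild is cheap relative to the rank test), `Q_T'` recomputed,
and the target retained iff the numerical rank equals `|T′|+1`.  Unreachable
targets have all-zero rows and are always discarded.  The driver may itself
be a target; its row is then `e_1` via the length-0 walk.  Full-rank row
subsets of `Q_T` form a linear matroid, so in exact arithmetic the greedy
returns a maximum-cardinality controllable subset, lexicographically best
under the ranking, and permuting the ranking changes `T′` but never `τ`.
Both properties are asserted against the oracle in the tests.

## Numerical choices

- **Rank.**  SVD with tolerance `max(n_rows, n_cols) · eps · σ_max`
  (overridable).  An all-zero matrix has rank 0.
- **log(q+1) stabilization.**  Applied elementwise after exact integer
  accumulation, default **on** for the stepwise pipeline.  The transform is
  nonlinear: proportional raw rows (e.g. `[1,2]` and `[2,4]`) become
  independent after the log, so all oracle comparisons run with the
  transform **off**, on raw counts small enough for float64 to hold
  exactly.  Divergences between log-on and log-off ranks are visible in the
  per-step logs rather than silently resolved.
- **Full-matrix baseline.**  The "standard approach" the reduction is
  compared against computes the rank of `Q_T` on the full network from raw
  counts (no reduction, no log): the log transform is part of this
  package's own stabilization, not of the baseline.  Raw counts beyond
  float64 range are clamped to the largest finite float; by then the
  baseline has already lost the information the clamp discards.
- **Exact oracle.**  Rank over the rationals by Bareiss fraction-free
  elimination on Python integers (no floating point, no tolerance), plus
  enumeration of all `2^S − 1` target subsets (guarded at `S ≤ 15`).
  "Best" subset = lexicographically earliest rank-position vector among the
  maximum-cardinality controllable subsets — the same preference the
  greedy encodes.

### A note on the tree benchmark

The benchmark is a full binary tree (edges parent→child) of `h` levels
(`2^h − 1` nodes, root = level 1) plus a cycle through the root and its two
children, one uniformly placed target per level, ranked root level first.
The default cycle wiring adds the two child→root back-edges; a directed
3-cycle variant (`root→c1→c2→root`) is available.  By construction (the
rows form a staircase in walk length) every per-level target is exactly
controllable from the root, and the reduced stepwise computation recovers
all of them at every height tested (2–12).  The raw full-matrix baseline is
provably well-conditioned at 63 nodes — its singular values are
`{2.8e9, 1.4e9, 0.58, 0.58, 0.38, 0.38}` whatever the target placement,
far above the SVD tolerance — and first becomes rank-deficient at 127
nodes (6 levels *below* the root), where closed-walk counts reach `~2^63`
and the tolerance, scaled by `σ_max ≈ 1.2e19`, swallows the small singular
values.  The benchmark narrative ("reduction rescues a deficient full-
matrix rank") is therefore anchored at the 127-node instance.

## Expression analyses

- **Activation** is the per-subject ratio pro-inflammatory / alert
  expression.  Genes with zero alert expression in any subject are excluded
  with a logged warning.  Subjects missing a condition are an error.
- **Fold change** `Δ = μ_MS / μ_HC` uses arithmetic means of per-subject
  ratios (not ratios of mean expression; the alternative reading is a
  one-line change at the call site since the activation table is exposed).
  `Δ` is strictly positive, yet under-activation must rank symmetrically
  with over-activation, so ranking and dysregulation operate on the signed
  score `δ = log2 Δ` by default; `use_log=False` restores raw-`Δ`
  semantics.
- **Ranking**: descending `|δ|`, ties broken by ascending gene id (a total
  order is required before the stepwise run).
- **Dysregulation**: `|δ|` strictly above the 75th percentile (linear
  interpolation between order statistics; percentile configurable).  Strict
  inequality means an all-tied score vector yields no calls.
- **Coactivation**: Spearman correlation of activation vectors within each
  group, tested only for pairs `(d, t)` with `t ∈ T′(d)`.  For `n ≤ 9`
  without ties the p-value is exact — the full `n!` permutation null is
  enumerated once and cached (at `n = 8` the achievable two-sided size
  just below 0.05 is 0.0458) — otherwise asymptotic, with average ranks for
  ties.  Raw `p < 0.05` is the default call, mirroring a screening (not
  confirmatory) design; Benjamini–Hochberg is available behind a flag.
  Differential coactivation is the symmetric difference of coactivated
  cells restricted to pairs controllable in both groups, so relabeling
  groups changes nothing.  Constant activation vectors give undefined rho
  and are reported not-significant with a warning.

## Robustness analysis

Attacks remove `round(intensity · N)` nodes or perturb `round(intensity ·
L)` edges, intensity up to 20% by default, 1,000 repetitions by default.
Preferential node removal draws sequentially without replacement with
probability ∝ `k` (high-degree) or ∝ `k_max + 1 − k` (low-degree — the
literal "∝ −k" is not a probability; this choice is strictly positive and
order-reversing).  Degree weights are computed once on the unperturbed
network per repetition; a switch recomputes them after every removal.
Edge attacks: uniform addition into free slots, uniform deletion, and
rewiring that keeps the tail and moves the head to a uniformly random
non-duplicating, non-self-loop endpoint (a move-tail variant is provided).

A driver is *lost* when it was removed, no target survives, or its `τ` on
the perturbed network is 0.  Since `τ > 0` iff some surviving target is
forward-reachable from the driver (a single reachable target always passes
its rank-1 test), the loss computation uses this exact reachability
criterion; `full_stepwise=True` re-runs the greedy instead and a test
asserts both paths agree.  Removed targets are dropped from the ranking
rather than counted as driver failure; a driver with no surviving targets
is lost.

## Synthetic data: what it does and does not emulate

`simulate_expression` reproduces the *structure* of the study data — two
groups (HC/MS, default 8 subjects each), two conditions per subject —
with log-normal baseline expression, a per-gene log-normal activation
effect (default 2-fold mean, spread 0.5 in log2), subject-level activation
noise (sd 0.5 in log2), and small alert-side measurement noise (sd 0.1 in
log2).  Dysregulation multiplies the MS activation of designated genes by
a stated fold; planted coactivation makes the target's activation noise a
`loading`-weighted copy of the driver's within designated groups, so the
pair's latent correlation equals the loading.  All planted parameters are
returned as ground truth.

Not emulated: count-based noise (the generator works on normalized
expression), library-size or batch effects, correlated null genes, and any
mechanistic link between the *network* and the expression covariance beyond
the explicitly planted pairs.  Passing recovery tests therefore shows the
estimators are consistent under the generative model, not that real data
meet its assumptions.

Problem sizes used in the shipped tests and benchmark script were chosen to
make every property checkable in minutes on one core: oracle comparisons at
`N ≤ 12`, `S ≤ 5` (200 seeded instances), the reduction-vs-baseline grid at
`N ∈ {50, 100, 150}` × density `{0.02, 0.05, 0.10}` × 5% targets × 20
repetitions, attack curves on an `N = 60`, density 0.05 fixture with 200
repetitions, and 500 Monte-Carlo replicates for the power and size of the
coactivation test.

## Known limitations

- The stepwise result can underestimate the exactly controllable count when
  the numerical rank misjudges an ill-conditioned reduced matrix; the
  per-step log records every rank decision so such cases are auditable.
- The brute-force oracle is exponential in `S` by design and guarded at
  `S ≤ 15`.
- Edge signs play no role in any computation; they are I/O metadata.
- The input edge list is taken as authoritative: no curation, no inference
  of missing interactions.
- Undirected networks are rejected rather than coerced.
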