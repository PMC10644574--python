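# Methods

## Problem and model

`mapalign` groups features detected in M LC–MS runs into consensus features.
Each run k contributes a partite of n_k deduplicated feature nodes plus one
placeholder node. Within a connected component of the relation graph, a
*linkage* selects one node per partite (placeholder = "analyte absent in
this run"); a feasible solution consists of p = max_k(n_k) + 1 matchings
such that matchings containing real nodes are pairwise distinct, no real
node appears twice, and every real node appears once. The all-placeholder
linkage pads solutions with multiplicity — with unbalanced partites this
padding is unavoidable, and we read the distinctness constraint as applying
only to matchings containing at least one real node.

A consequence worth stating explicitly: because the placeholder-containing
constraints fix both p and the real nodes, **every** feasible solution of a
component contains exactly Σ_k (p − n_k) placeholders, and the number of
matchings containing real nodes can never exceed p. The first fact makes the
optimal *matchings* provably independent of the placeholder penalty w_p
(asserted as a test); the second is an active constraint the solvers must
enforce — an all-singletons partition of a 2×2 component, for example, needs
4 matchings but only p = 3 exist, so it is infeasible.

### Cost model

For a matching, the subgraph induced on its real picks (using only edges
present in the component) is priced as:

* distribution cost — total weight of the minimum spanning **forest**
  (an MST per connected cluster). When the picks are disconnected the MST
  has fewer edges than expected; the missing structure is charged through
* connectivity cost `w_c · N_c` (N_c = number of connected clusters) and
* missing-node cost `w_p · N_p` (N_p = placeholder count),
* minus a bonus `b` for connected full matchings (N_p = 0 and N_c = 1),
  which gives complete groups priority when competing for nodes.

A solution costs the sum over its p matchings; an all-placeholder matching
costs `w_p · M`.

The factor values are tunables with no single published setting; the package
defaults are `w_c = 1.0`, `w_p = 1.0`, `b = 0.5` (config keys
`cost.{w_c, w_p, bonus}`). Sensitivity: w_p is immaterial to the exact
optimum (above); w_c sets the price of splitting a neighborhood into
separate groups relative to edge weights (which live in [0, 1] inside the
tolerance window) — values ≥ 1 make merging within tolerance essentially
always preferable; b breaks ties in favor of complete groups and must stay
below w_c to keep the bonus from subsidizing bad edges.

### Edge weights

`w(e) = (|Δm/z|/tol_mz + |ΔRT|/tol_RT + 1 − min(ña)/max(ña)) / 3`, with
closed (≤) tolerance comparisons. Areas are normalized per component-partite
(largest same-run area inside the component); a partite whose maximum area
is zero degenerates to all ones with a warning. m/z tolerance is absolute Da
by default; in ppm mode the window is evaluated at the smaller m/z of the
pair. Weights are symmetric and lie in [0, 1] for in-tolerance pairs.

## Solvers

**Exact.** The MAP is a set-partitioning problem: each linkage is a column
covering its real picks. The solver enumerates all linkages of a component
(guarded; default `solver.exact_limit = 20000` columns), then runs a
depth-first branch-and-bound over partitions of the node set, with an
admissible bound that charges every uncovered node its cheapest per-node
share of any column containing it. Ties between optima resolve to the
lexicographically smallest sorted matching multiset, making results
platform-stable. The brute-force cross-checks (exhaustive enumeration of all
feasible partitions, and the same model given to an independent ILP backend)
live in the test suite.

**Greedy.** All linkage costs are computed up front; the cheapest remaining
matching (ties: lexicographically smallest tuple) is committed and every
linkage sharing one of its nodes invalidated, until all nodes are used. A
candidate is skipped when committing it would leave fewer free matchings
than the largest remaining partite requires. Greedy protects the best
individual matchings at the expense of global cost; the test suite fixtures
an instance where this is strictly suboptimal.

**VLSNS.** Very large-scale neighborhood search over the permutation
representation: each partite's node list is padded with placeholders to
length p; row j of the permutation stack is matching j. One move
re-optimizes a single partite by solving a p×p linear assignment problem
(entries → matchings, each cell a memoized matching cost) and applies the
best-improving partite; iteration stops at a local optimum (every accepted
move strictly decreases cost, so termination is guaranteed) or after
`max_iterations` (default 100). Costs are computed on demand — no full
enumeration — which is what lets this solver scale.

Multi-start initialization: **MSR** draws independent uniform permutations;
**MSG** draws `n_starts` random bases (default 8) and expands each into
`grid_factor` (default 4) variants by cyclically rolling every partite's
permutation by ⌊j·p/grid_factor⌋. The grid spreads starts across the
permutation space instead of relying on randomness alone; with the default
32 starts the search reached the exact optimum on ≥ 95% of random test
instances (asserted as a stochastic, seeded test). Best-improvement rather
than first-improvement partite updates are used.

**Dispatch.** `solver.method = auto` (default) uses the exact solver when
the linkage count is at most `exact_limit` and VLSNS otherwise. The LAP
subroutine is scipy's modified Jonker–Volgenant algorithm; infinite cells
are handled by a big-M reduction so the assignment has maximum cardinality
among finite cells, then minimum cost. LAP ties resolve deterministically
for a given matrix (the backend is deterministic), which is the determinism
contract the pipeline needs.

## RT registration

Linear RANSAC only. Anchor pairs are target features with exactly one
reference feature inside (mz_tol, anchor window); ambiguous targets are
skipped. The anchor RT window defaults to max(1 min, 10·rt_tol): it must
cover the *inter-run drift*, which is typically several times the final
matching tolerance — a window tied to the matching tolerance truncates
anchors at the gradient ends and biases the fit. Each RANSAC iteration
(default 1000) fits a line through two random anchors and counts inliers
within `inlier_threshold` (default rt_tol/2); the best model (most inliers,
ties by inlier RSS) is refit by least squares on its inliers. Fewer than
`min_inliers` (default max(10, 10% of anchors)) triggers a fallback to the
identity model with a warning rather than a hard failure. Nonlinear
residual drift is deliberately left to the matcher.

## Scaling

Components above `scaling.node_limit` (default 50, keeping exact/greedy
enumeration tractable) are bisected by run: the cut between
acquisition-adjacent run groups that best balances node counts, recursively.
Sub-solutions are merged agglomeratively: candidate matching pairs from
different groups are scored by their minimum connecting edge weight in the
full component and merged in ascending order (recomputing distances after
each merge, to closure) while their run coverages are disjoint. If more than
p clusters remain after edge-connected merging, cheapest run-disjoint pairs
are merged without requiring an edge so the solution-size constraint holds.
Merging by cheapest bridge is exact when each matching pair is joined by a
single bridge (asserted); otherwise it is a documented approximation.

Recursive folder alignment aligns each subfolder's tables, carries each
consensus group upward as one representative feature (arithmetic mean of
member m/z, RT and area), and repeats up the tree; leaf provenance (run
name, feature id) is preserved. A single-run folder passes its features
through unchanged.

## Evaluation scheme

For each annotated analyte, the predicted matching sharing the most
(run, feature) entries is its corresponding matching (ties: fewer total
features, then lexicographic content). Each analyte × run cell receives
exactly one label: TP (same feature), FP (spurious **or wrong** feature —
a wrong feature is a single FP, not FP+FN, so counts always total
analytes × runs), TN (absent in both), FN (missed feature). Metrics:
P = TP/(TP+FP), R = TP/(TP+FN), F1 = harmonic mean, feature accuracy
(TP+TN)/total, analyte accuracy = fraction of analytes whose whole row is
TP/TN. Zero denominators report 0 with a warning. Display rounding is
half-even to 3 decimals. Annotation transfer onto another feature set ranks
in-window candidates by (Δm/z/tol_mz)² + (ΔRT/tol_RT)², one candidate per
analyte per run, closest first.

## Synthetic benchmark

The generator plants `n_analytes` (default 100) uniformly in m/z 100–1000 Da
and RT 1–14 min (optional minimum pairwise separation, off by default), with
log-normal base areas. Per run (default 6): affine drift with slope in
[0.97, 1.03] and intercept in [−0.2, 0.2] min, optional low-frequency
sinusoidal perturbation (amplitude default 0 — when enabled it emulates
nonlinear drift the linear correction cannot absorb, stressing the matcher),
Gaussian jitter (m/z sd 0.002 Da = tol/5, RT sd 0.02 min = tol/5),
log-normal intensity noise (sigma 0.3), Bernoulli dropout (p = 0.05), and
round(0.5 · n_analytes) decoy features, uniform by default or within twice
the tolerances of true features in `hard_mode`. The exact generated feature
of every analyte in every run is exported as the annotation.

What the generator does *not* emulate: chromatographic peak shapes, adducts
and isotope envelopes, correlated (batch-structured) drift, heteroscedastic
m/z error, or intensity-dependent dropout. Passing the recovery tests
therefore demonstrates the correctness of the registration + matching
machinery under controlled drift/noise/decoy conditions, not performance on
real instrument data.

## Numerical and determinism choices

Float comparisons in solvers use an absolute epsilon of 1e-9; tolerance
comparisons are closed. Components are ordered by (min m/z, min RT), ties
everywhere break lexicographically, and per-component VLSNS seeds derive
from the job seed and component index, so identical config + seed gives
byte-identical output. Degenerate inputs: empty components cost 0;
a single-node component resolves to a singleton matching plus one empty
matching; zero-area partites normalize to 1.

## Known limitations

* The merge step after forced segmentation is exact only for single-bridge
  structures; densely bridged components can merge suboptimally.
* Greedy can exceed the optimal cost by a factor growing with component
  size; it is kept for its robustness on noisy feature sets and for speed.
* Profile-based (raw spectra) warping and nonlinear RT models are out of
  scope; only affine RANSAC registration is provided.
* No adduct/isotope awareness: correspondence is purely geometric plus
  intensity.
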