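# Methods

## The model

A gene family evolving strictly vertically has a gene tree congruent with
its species tree. Four processes break congruence: gene duplication (D),
horizontal transfer (T), gene loss (L), and incomplete lineage sorting
(ILS, also called deep coalescence). `dtli` reconciles a rooted *binary*
gene tree `T_G` with a rooted species tree `T_S` that may contain
polytomies, under a parsimony criterion

    pi = delta * n_D + tau * n_T + lambda * n_L

where speciations (co-divergence at a binary species node) and deep
coalescences (co-divergence at a polytomy) are free. A polytomy marks a
region of the species tree where the branching order was rapid or
unresolved, so ILS is entertained there: any gene-tree branching pattern
consistent with *some* binary resolution of the polytomy is explained at
zero cost. Users can collapse short species-tree edges to state where ILS
should be considered; at binary nodes incongruence is always attributed
to duplication or transfer.

Every internal gene node `g` is annotated with the species `M(g)` that
contained it and the event at its divergence; every gene edge carries its
loss records; a transfer edge `(u, v)` has donor `M(u)` and recipient
`M(v)`, which must be phylogenetically incomparable. The package
enumerates **all** minimum-cost histories, then filters them for temporal
feasibility.

### The duplication test

For a candidate assignment of `g` to `s` with children assigned
`(s1, sigma1)` and `(s2, sigma2)`, each child's *vertical inheritance
set* is projected onto the children of `s`: a transfer child projects to
the empty set, a child at `s` itself contributes its own sigma-hat
(the set of children of `s` that vertically inherit one of its
descendants), and a child strictly below contributes the child branch of
`s` it descends through. If the two projections intersect, some lineage
of `s` inherits two descendants of `g` and the divergence must be a
**duplication**. Disjoint projections mean a **transfer** if one child is
incomparable to `s`, otherwise a **speciation** (binary `s`) or
**coalescence** (polytomy). At binary nodes this reduces exactly to
classical lca reconciliation.

### Candidate space and the origination convention

Node assignments are derived from the children rather than enumerated
freely: a co-divergence or duplication sits at `lca(s1, s2)` — above the
lca both projections fall into a single child branch and always
intersect, and a duplication placed higher only adds losses — and a
transfer node sits at its vertical child's species, the donor. This
keeps the all-optimal solution count finite and meaningful for the
DT/DTI variants, where the loss term is not scored and "floating"
duplications would otherwise tie endlessly.

The gene root is subject to an origination convention: the ancestral
locus is assumed to reside in a lineage ancestral to **every** sampled
copy, so `M(root)` must be an ancestor-or-equal of the lca of all mapped
species, transfer-acquired copies included. This generalizes the
lca-rooting convention of classical duplication–loss reconciliation.
Without it, the four-taxon worked example (below) would admit a
zero-loss single-transfer history whose root "originates" inside the
polytomy, and the classical two-optimum structure of that instance would
disappear.

### The loss heuristic

Losses are reconstructed per gene edge by a deterministic walk:

* A lineage descending from its parent's species crosses one species
  divergence per level; each crossing charges one loss labeled with the
  crossed node's uncovered children. At a polytomy the whole uncovered
  set is one loss: it is a clade in some binary resolution and can be
  lost as a unit.
* An edge that **enters** a node fresh (from an ancestral branch or by a
  transfer landing) whose occupant covers only a proper subset of the
  children is charged one terminal loss for the uncovered set.
* A chained co-divergence at the same species inherits exactly its
  parent's allocation and is never charged.
* A re-emitting node (duplication or transfer) charges the crossings of
  its **own** species' divergence within its own sigma-hat, not within
  the full child set (and drops empty charges): copies of a family
  confined to part of a polytomy sort through a resolution of that part
  only; the complement was already charged once, on the edge that
  entered the polytomy. Because the gene root has no incoming edge, a
  family rooted at a polytomy is automatically charged as if it
  originated inside its cheapest binary resolution.

At internal binary nodes sigma-hat is always the full child pair, so the
rule reduces to the textbook bypassed-sibling count. On the worked
example it reproduces the expected totals: the duplication history loses
`A`, `{B}` and `{C,D}` (three losses), the transfer history loses only
`{B}`.

## The two-pass algorithm

**firstPass** fills, in gene-tree post-order, a cost table and a history
table keyed by `(s, sigma_hat, mode)`. The `mode` bit records whether
the node consumes its species by co-divergence or re-emits copies from
within the branch; it is part of the key because the parent edge's loss
count depends on it (a fresh lineage co-diverging over part of a
polytomy is charged the uncovered set; a chained co-divergence is not).
All argmin candidates are stored at every key — no tie-breaking — along
with exact history counts, so `firstPass` reports the optimal score, the
optimal root assignments and the exact number of optimal histories.

**secondPass** traverses every unique path through the history tables in
pre-order, materializing each optimal history exactly once with full
annotations (node map, events, loss records, transfer edges), in a
deterministic order. Each history is independently rescored from its
annotations and checked against the DP optimum. Two histories are
considered the same iff node maps, events, transfer edges and canonical
loss labels all coincide; with assignments derived as above, a history
is uniquely determined by its node map. Enumeration is capped
(default 10,000) with an explicit truncation flag; counts remain exact.

## Temporal feasibility

Each transfer requires its donor and recipient branches to have
coexisted. A history is feasible iff the directed *timing graph* over
transfer donors/recipients is acyclic. Edges come in three classes:
(1) species-tree ancestry between involved vertices; (2) for transfers
on comparable gene nodes (including a transfer with itself), edges from
the parents of the earlier transfer's donor and recipient to the later
transfer's donor and recipient — the branch-overlap constraints; (3)
contemporaneity propagation: a species strictly ancestral to one partner
of a transfer precedes the other partner. Class 3 uses *strict*
ancestry; with ancestry-or-equal every transfer would impose the cycle
`d -> r -> d` and nothing would ever be feasible. Classes 2 and 3 may
reference parents that are not themselves donors or recipients; these
vertices have no incoming edges from elsewhere and cannot create new
cycles, so they are simply included in the graph. The class-3 rule
depends only on species-tree ancestry, not on graph paths, so a single
pass is already its fixpoint. Acyclicity is decided by topological sort
(via networkx) in linear time.

Feasibility is evaluated post hoc on each optimal history; infeasible
ones are flagged and excluded from the reported set. When *every*
optimum is infeasible the solution set is marked
`all_optimal_infeasible`; searching for an optimal feasible history in
that regime is a much harder problem and is not attempted.

## Survey protocol, rooting, highways

`batch_reconcile` applies the retention protocol used in genome-scale
surveys: per (model, transfer-cost) cell, a tree is excluded if it has
no temporally feasible optimal history (by default a tree failing
anywhere is excluded everywhere, the conservative convention for cross-model
comparisons; a
per-cell policy is available), and excluded as *degenerate* if its
feasible optima disagree in any event count — aggregate statistics from
such trees would depend on an arbitrary choice among optima. Retained
counts are summed per cell; bookkeeping satisfies
`retained + infeasible + degenerate (+ errors) = input trees` in every
cell. Models without ILS require a binary species tree, so a batch may
supply one tree per model (typically the binary tree and its collapsed
version).

Rooting by event parsimony evaluates the tree re-rooted on each of the
`2n-3` edges of its unrooted topology and returns every rooting
achieving the minimum, each with its full solution set.

Transfer matrices sum transfers between unordered species pairs (both
directions folded) over the retained trees of one cell, using the first
feasible history of each tree (deterministic, and count-equivalent by
the retention rule). The pair universe is every unordered incomparable
pair of non-root species nodes, zeros included; ancestral lineages are
keyed by their node labels. A *highway* is a pair whose count strictly
exceeds `mean + 1.5 * SD`, with mean and population SD taken over the
whole universe. Including zeros and using the population SD are
documented choices (both configurable upstream of the detector, which
takes any matrix); detection is invariant under rescaling all counts.

## The simulator

`synthetic.simulate_history` evolves gene copies root-to-leaves. Per
copy per species branch, duplication/transfer/loss counts are drawn from
Poisson laws with the configured per-branch expectations (defaults 0.1
each; the survey-style acceptance batch uses 0.08/0.15/0.1 to emulate a
transfer-dominant prokaryotic regime). Duplications copy a lineage in
place (the new copy redraws events for the branch remainder), transfers
move a copy to a uniformly chosen incomparable species branch, losses
terminate a copy. Each lineage crossing a polytomy sorts through an
independently drawn uniformly random binary resolution (hard-polytomy
semantics); a shared-resolution mode models soft polytomies. Every
random choice is recorded as an instruction list, and a separate
deterministic interpreter (`replay`) rebuilds the gene tree from the
instructions alone, so planted histories are exactly replayable.

What the simulator does *not* model: branch lengths, population sizes or
coalescent ILS probabilities (events are placed per-branch, not
per-time); sequence evolution; transfer recipients weighted by
divergence time. Tests passing on these simulations therefore certify
the combinatorial machinery, not calibration against any real dataset.

The brute-force oracle exploits the fact that, once every internal gene
node is assigned a species, the transfer edges, events, inheritance sets
and losses are all uniquely determined bottom-up: enumerating all
assignments (guarded to <= 6 gene leaves and <= 11 species nodes)
enumerates all candidate histories. It shares no code with the DP and
serves as the independent ground truth in the test suite, where the DP
and traceback must reproduce its optimal score, count and full solution
set exactly on hundreds of random instances.

## Numerical and engineering choices

* Costs are user floats compared exactly; the test suite draws random
  costs from quarter-integer grids so that sums are exact in binary
  floating point regardless of association order. `inf` as transfer
  cost disables transfers (a saturating sentinel; invalid candidates
  are never stored).
* Node ids are assigned in deterministic post-order from the input
  text; candidate lists and root keys are sorted canonically, so
  enumeration order and all outputs are reproducible across runs.
* Species trees with a polytomy of out-degree above 12 are refused
  unless forced: the key space grows as `2^k` per polytomy.
* Scale: reconciliations at survey scale (21 species nodes, polytomies
  to out-degree 6, ~20-copy families) run in milliseconds per solution;
  test-suite sweeps use hundreds of instances with <= 5 gene leaves and
  <= 9 species nodes so the oracle remains exhaustive, and the
  acceptance batch simulates 60 families on 11 species — sizes chosen
  to keep the exhaustive cross-checks exact.

## Known limitations and negative results

* **Collapse monotonicity has a scope.** Collapsing a species edge
  never increases the optimum for duplication–loss–ILS reconciliation,
  and, with transfers, whenever some optimal history avoids the
  collapsed node as a transfer endpoint. It can genuinely increase the
  optimum otherwise: a transfer *into the collapsed branch* is no
  longer expressible once that branch vanishes into a polytomy
  (e.g. gene `((g2_C,g3_B),(g0_A,(g1_C,g4_B)))` vs species `(A,(B,C))`
  at `delta=3.5, lambda=5.5, tau=4.75`: unique optimum is one transfer
  `A -> (B,C)` at 4.75; after collapsing `(B,C)` exhaustive enumeration
  gives 9.0). The monotonicity tests assert the property in its valid
  scope.
* **The parsimony bound on planted histories has the same flavor.** The
  optimum is bounded by the planted cost whenever the surviving root
  divergence lies in a lineage ancestral to all sampled copies; a
  family whose survivors all descend from a side-branch transfer
  violates the origination convention and may be reconstructed at
  higher cost (`synthetic.visible_root_species` exposes the check).
* Degeneracy is assessed on event-count agreement of *feasible* optima,
  the finest granularity the retention protocol needs; histories that
  differ only in lineage placements with identical counts are retained.
* When all optima are temporally infeasible the package reports the
  fact rather than searching for an optimal feasible history.
* Multi-gene transfer events and unsampled ("ghost") donor lineages are
  outside the model.
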