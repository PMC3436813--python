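"""Synthetic data: species trees, gene trees with planted D/T/L/ILS
histories, and a brute-force reconciliation oracle.

The simulator evolves gene lineages root-to-leaves over a species tree.
Per gene copy per species branch, duplication/transfer/loss event counts
are drawn from Poisson laws with the configured per-branch expectations;
duplications copy a lineage in place, transfers move a copy to a
uniformly chosen incomparable species branch, losses terminate a lineage.
At a species polytomy each surviving lineage sorts through a uniformly
random binary resolution drawn independently per lineage (hard-polytomy
semantics; a shared-resolution "soft" mode is available). Every random
choice is recorded as an explicit instruction list, and a separate
deterministic interpreter (:func:`replay`) reconstructs the gene tree
from the instructions alone, so planted histories are exactly replayable.

The oracle exploits the fact that, given a full assignment of internal
gene nodes to species nodes, the transfer edges, events, inheritance sets
and loss records are all uniquely determined bottom-up; enumerating all
assignments therefore enumerates all candidate histories. It shares no
code with the dynamic program.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .model import (CODIV, COALESCENCE, DUPLICATION, EMIT, LEAF, SPECIATION,
                    TRANSFER, CostScheme, LossRecord, effective_costs,
                    model_allows_ils)
from .solutions import ReconciliationHistory, SolutionSet, TransferEdge
from .trees import (GENE, SPECIES, LeafMapping, RootedTree, SpeciesIndex,
                    build_species_index, collapse_edge,
                    leaf_mapping_from_suffix)

__all__ = [
    "SimulationConfig", "PlantedHistory", "simulate_history",
    "simulate_until_viable", "replay", "random_species_tree",
    "random_binary_resolution", "gene_tree_from_resolution",
    "identity_mapping", "random_instance", "brute_force_reconcile",
    "feasible_by_exhaustion",
]

ORACLE_MAX_GENE_LEAVES = 6
ORACLE_MAX_SPECIES_NODES = 11


# ---------------------------------------------------------------------------
# random trees


def random_species_tree(n: int, polytomy_size: Optional[int] = None,
                        seed: int = 0,
                        labels: Optional[list[str]] = None) -> RootedTree:
    """A random binary species topology on ``n`` leaves (uniform random
    join order), optionally with internal edges collapsed under one node
    until it becomes a polytomy of the requested out-degree."""
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if labels is None:
        labels = [f"s{i+1}" for i in range(n)]
    rng = np.random.default_rng(seed)
    items: list = list(labels)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        items.append(([a, b], None))
    tree = RootedTree.from_nested(items[0], SPECIES)
    if polytomy_size is None or polytomy_size <= 2:
        return tree
    if polytomy_size > n:
        raise ValueError(f"polytomy size {polytomy_size} exceeds leaf "
                         f"count {n}")

    def _cluster(t: RootedTree, i: int) -> frozenset:
        nd = t.nodes[i]
        if nd.is_leaf:
            return frozenset([nd.label])
        return frozenset().union(*(_cluster(t, c) for c in nd.children))

    eligible = [i for i in tree.postorder()
                if not tree.is_leaf(i)
                and len(_cluster(tree, i)) >= polytomy_size]
    target_cluster = _cluster(tree,
                              eligible[int(rng.integers(0, len(eligible)))])
    while True:
        node = next(i for i in tree.postorder()
                    if not tree.is_leaf(i)
                    and _cluster(tree, i) == target_cluster)
        if len(tree.children(node)) >= polytomy_size:
            break
        internal_kids = [c for c in tree.children(node)
                         if not tree.is_leaf(c)]
        pick = internal_kids[int(rng.integers(0, len(internal_kids)))]
        tree = collapse_edge(tree, pick)
    return tree


def random_binary_resolution(species_tree: RootedTree,
                             seed: int = 0) -> RootedTree:
    """A uniformly random full binary resolution of every polytomy
    (random sequential joining of child subtrees); same leaf labels."""
    rng = np.random.default_rng(seed)

    def rec(i: int):
        nd = species_tree.nodes[i]
        if nd.is_leaf:
            return nd.label
        parts = [rec(c) for c in nd.children]
        while len(parts) > 1:
            a_i, b_i = sorted(rng.choice(len(parts), size=2, replace=False))
            b = parts.pop(b_i)
            a = parts.pop(a_i)
            parts.append(([a, b], None))
        return parts[0]

    return RootedTree.from_nested(rec(species_tree.root), SPECIES)


def gene_tree_from_resolution(resolution: RootedTree) -> RootedTree:
    """Reinterpret a binary species topology as a congruent gene tree
    (one gene copy per species, leaf labels shared)."""
    return RootedTree.from_nested(resolution._nested(resolution.root), GENE)


def identity_mapping(gene_tree: RootedTree,
                     species_tree: RootedTree) -> LeafMapping:
    """Map gene leaves to the species leaves with the same label."""
    pairs = {l: species_tree.leaf_id(gene_tree.label(l))
             for l in gene_tree.leaves()}
    return LeafMapping(pairs, gene_tree, species_tree)


# ---------------------------------------------------------------------------
# simulation with replayable planted histories


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated gene family. Rates are expected
    events per gene copy per species branch (dimensionless Poisson
    means). ``ils`` is "independent" (each lineage crossing a polytomy
    sorts through its own uniformly random binary resolution; hard
    polytomy) or "shared" (one resolution per polytomy per family; soft
    polytomy)."""

    species_tree: RootedTree
    dup_rate: float = 0.1
    trans_rate: float = 0.1
    loss_rate: float = 0.1
    ils: str = "independent"
    seed: int = 0

    def __post_init__(self):
        for name in ("dup_rate", "trans_rate", "loss_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ils not in ("independent", "shared"):
            raise ValueError("ils must be 'independent' or 'shared'")


@dataclass
class PlantedHistory:
    """The ground truth of one simulated family: the instruction list that
    deterministically rebuilds the gene tree, plus per-event summaries.
    ``gene_tree`` is None when the family went extinct (or left a single
    copy, too few to form a binary tree)."""

    config: SimulationConfig
    instructions: list
    gene_tree: Optional[RootedTree]
    mapping: Optional[LeafMapping]
    duplications: list = field(default_factory=list)   # species ids
    transfers: list = field(default_factory=list)      # (donor, recipient)
    losses: list = field(default_factory=list)         # species ids
    n_ils_splits: int = 0

    @property
    def extinct(self) -> bool:
        return self.gene_tree is None

    def planted_cost(self, costs: CostScheme) -> float:
        """Score of the planted events under a cost scheme; an upper bound
        on the parsimony optimum of the resulting gene tree."""
        total = costs.dup * len(self.duplications) + \
            costs.trans * len(self.transfers)
        if costs.losses_in_score:
            total += costs.loss * len(self.losses)
        return total


def simulate_history(config: SimulationConfig) -> PlantedHistory:
    """Run one simulation; deterministic given ``config.seed``."""
    S = config.species_tree
    index = build_species_index(S, force=True)
    rng = np.random.default_rng(config.seed)
    instructions: list = []
    dups: list[int] = []
    transfers: list[tuple[int, int]] = []
    losses: list[int] = []
    ils_splits = [0]
    counter = itertools.count()
    leaf_counter = itertools.count()
    shared_res: dict[int, object] = {}

    incomp = {s: [v for v in range(len(S)) if index.incomparable(s, v)]
              for s in range(len(S))}

    def new_lin() -> int:
        return next(counter)

    def resolve(s: int):
        parts: list = list(S.children(s))
        while len(parts) > 1:
            i, j = sorted(rng.choice(len(parts), size=2, replace=False))
            b = parts.pop(j)
            a = parts.pop(i)
            parts.append((a, b))
        return parts[0]

    def combine(l, r):
        if l is None:
            return r
        if r is None:
            return l
        return ([l, r], None)

    def sim_branch(lin: int, s: int):
        n_d = rng.poisson(config.dup_rate)
        n_t = rng.poisson(config.trans_rate)
        n_l = rng.poisson(config.loss_rate)
        seq = ["D"] * n_d + ["T"] * n_t + ["L"] * n_l
        if len(seq) > 1:
            seq = [seq[i] for i in rng.permutation(len(seq))]
        return sim_events(lin, s, seq)

    def sim_events(lin: int, s: int, seq: list):
        if not seq:
            return sim_arrival(lin, s)
        ev, rest = seq[0], seq[1:]
        if ev == "L":
            instructions.append(("loss", lin, s))
            losses.append(s)
            return None
        if ev == "D":
            a, b = new_lin(), new_lin()
            instructions.append(("dup", lin, s, a, b))
            dups.append(s)
            left = sim_events(a, s, rest)
            right = sim_branch(b, s)
            return combine(left, right)
        # transfer: pick an incomparable recipient branch, if any exists
        cands = incomp[s]
        if not cands:
            return sim_events(lin, s, rest)
        r = int(cands[int(rng.integers(0, len(cands)))])
        a, b = new_lin(), new_lin()
        instructions.append(("transfer", lin, s, a, b, r))
        transfers.append((s, r))
        left = sim_events(a, s, rest)
        right = sim_branch(b, r)
        return combine(left, right)

    def sim_arrival(lin: int, s: int):
        if S.is_leaf(s):
            name = f"g{next(leaf_counter)}_{S.label(s)}"
            instructions.append(("sample", lin, s, name))
            return name
        kids = S.children(s)
        if len(kids) == 2:
            a, b = new_lin(), new_lin()
            instructions.append(("speciation", lin, s, a, b))
            return combine(sim_branch(a, kids[0]), sim_branch(b, kids[1]))
        if config.ils == "shared":
            res = shared_res.setdefault(s, resolve(s))
        else:
            res = resolve(s)
        return descend(lin, s, res)

    def descend(lin: int, s: int, res):
        if not isinstance(res, tuple):
            return sim_branch(lin, int(res))
        a, b = new_lin(), new_lin()
        instructions.append(("ils_split", lin, s, a, b,
                             _res_leaves(res[0]), _res_leaves(res[1])))
        ils_splits[0] += 1
        return combine(descend(a, s, res[0]), descend(b, s, res[1]))

    nested = sim_branch(new_lin(), S.root)
    gene_tree = None
    mapping = None
    if nested is not None and not isinstance(nested, str):
        gene_tree = RootedTree.from_nested(nested, GENE)
        mapping = leaf_mapping_from_suffix(gene_tree, S)
    return PlantedHistory(config, instructions, gene_tree, mapping,
                          dups, transfers, losses, ils_splits[0])


def _res_leaves(res) -> tuple:
    if not isinstance(res, tuple):
        return (int(res),)
    return _res_leaves(res[0]) + _res_leaves(res[1])


def replay(species_tree: RootedTree, instructions: list
           ) -> Optional[RootedTree]:
    """Rebuild the gene tree from a planted instruction list alone
    (no randomness): split instructions branch a lineage, losses kill it,
    samples name surviving leaves; dead subtrees are pruned and
    pass-through lineages suppressed. Returns None on extinction."""
    splits: dict[int, tuple[int, int]] = {}
    terminal: dict[int, Optional[str]] = {}
    roots_seen = set()
    all_children = set()
    for ins in instructions:
        kind = ins[0]
        lin = ins[1]
        roots_seen.add(lin)
        if kind in ("dup", "speciation", "ils_split"):
            splits[lin] = (ins[3], ins[4])
            all_children.update((ins[3], ins[4]))
        elif kind == "transfer":
            splits[lin] = (ins[3], ins[4])
            all_children.update((ins[3], ins[4]))
        elif kind == "loss":
            terminal[lin] = None
        elif kind == "sample":
            terminal[lin] = ins[3]

    root_candidates = roots_seen - all_children
    if not root_candidates:
        return None
    root = min(root_candidates)

    def build(lin: int):
        if lin in splits:
            a, b = splits[lin]
            left, right = build(a), build(b)
            if left is None:
                return right
            if right is None:
                return left
            return ([left, right], None)
        return terminal.get(lin)

    nested = build(root)
    if nested is None or isinstance(nested, str):
        return None
    return RootedTree.from_nested(nested, GENE)


def visible_root_species(planted: PlantedHistory) -> Optional[int]:
    """The species branch carrying the deepest divergence that survives
    pruning -- i.e. where the root of the returned gene tree lived.

    The parsimony bound "DP optimum <= planted cost" is guaranteed only
    when this species is an ancestor-or-equal of the lca of all sampled
    species: the inference model assumes the family originated in a
    lineage ancestral to every sampled copy, so a surviving root produced
    by, say, a transfer among side branches is reconstructed differently
    (and possibly at higher cost) than it was planted.
    """
    splits: dict[int, tuple[int, int, int]] = {}
    terminal: dict[int, Optional[str]] = {}
    children = set()
    lineages = set()
    for ins in planted.instructions:
        kind, lin = ins[0], ins[1]
        lineages.add(lin)
        if kind in ("dup", "speciation", "ils_split"):
            splits[lin] = (ins[3], ins[4], ins[2])
            children.update((ins[3], ins[4]))
        elif kind == "transfer":
            splits[lin] = (ins[3], ins[4], ins[2])
            children.update((ins[3], ins[4]))
        elif kind == "loss":
            terminal[lin] = None
        elif kind == "sample":
            terminal[lin] = ins[3]

    def survives(lin: int) -> bool:
        if lin in splits:
            a, b, _ = splits[lin]
            return survives(a) or survives(b)
        return terminal.get(lin) is not None

    roots = lineages - children
    if not roots:
        return None
    lin = min(roots)
    while True:
        if lin not in splits:
            return None
        a, b, species = splits[lin]
        sa, sb = survives(a), survives(b)
        if sa and sb:
            return species
        if sa:
            lin = a
        elif sb:
            lin = b
        else:
            return None


def simulate_until_viable(config: SimulationConfig,
                          max_tries: int = 100) -> PlantedHistory:
    """Retry with derived seeds until the family survives with >= 2
    copies."""
    for i in range(max_tries):
        planted = simulate_history(replace(config,
                                           seed=config.seed + 1009 * i))
        if not planted.extinct:
            return planted
    raise RuntimeError(
        f"no surviving family in {max_tries} tries; loss rate too high?")


# ---------------------------------------------------------------------------
# brute-force reconciliation oracle


def brute_force_reconcile(gene_tree: RootedTree, species_tree: RootedTree,
                          mapping: LeafMapping, costs: CostScheme,
                          model: str = "DTLI") -> SolutionSet:
    """Exhaustively enumerate all assignments of species nodes to internal
    gene nodes, score every valid history, and return the full argmin set.

    Guarded to small instances (<= 6 gene leaves, <= 11 species nodes);
    independent of the dynamic-programming code path.
    """
    if len(gene_tree.leaves()) > ORACLE_MAX_GENE_LEAVES:
        raise ValueError("oracle guard: too many gene leaves")
    if len(species_tree) > ORACLE_MAX_SPECIES_NODES:
        raise ValueError("oracle guard: species tree too large")
    index = build_species_index(species_tree)
    if not model_allows_ils(model) and index.k_star > 2:
        raise ValueError(f"model {model} requires a binary species tree")
    eff = effective_costs(costs, model)
    S = species_tree
    G = gene_tree
    internals = [g for g in G.postorder() if not G.is_leaf(g)]

    # origination convention: the root divergence maps at or above the lca
    # of all mapped species
    mapped = sorted({s for _, s in mapping.items()})
    lca_all = mapped[0]
    for s in mapped[1:]:
        lca_all = index.lca(lca_all, s)

    best: float = math.inf
    argmin: list[ReconciliationHistory] = []
    for combo in itertools.product(range(len(S)), repeat=len(internals)):
        M = {g: s for g, s in zip(internals, combo)}
        if not index.is_ancestor(M[G.root], lca_all):
            continue
        for l in G.leaves():
            M[l] = mapping[l]
        hist = _oracle_evaluate(G, S, index, M, eff)
        if hist is None or math.isinf(hist.score):
            continue
        if hist.score < best:
            best = hist.score
            argmin = [hist]
        elif hist.score == best:
            argmin.append(hist)
    argmin.sort(key=lambda h: h.canonical())
    return SolutionSet(best, argmin, len(argmin))


def _oracle_evaluate(G: RootedTree, S: RootedTree, index: SpeciesIndex,
                     M: dict, costs: CostScheme
                     ) -> Optional[ReconciliationHistory]:
    sig: dict[int, frozenset] = {}
    mode: dict[int, int] = {}
    events: dict[int, str] = {}
    losses: dict[int, tuple] = {}
    transfers: list[TransferEdge] = []
    for g in G.postorder():
        if G.is_leaf(g):
            sig[g] = frozenset((M[g],))
            mode[g] = LEAF
            continue
        s = M[g]
        kids = G.children(g)
        horiz = []
        projs = []
        for c in kids:
            sc = M[c]
            if index.incomparable(s, sc):
                horiz.append(True)
                projs.append(frozenset())
            elif index.is_ancestor(s, sc):
                horiz.append(False)
                projs.append(sig[c] if sc == s else
                             frozenset((index.child_toward(s, sc),)))
            else:
                return None  # child mapped to a proper ancestor
        if horiz[0] and horiz[1]:
            return None
        # candidate-space restriction: a transfer node sits at its
        # vertical child's species (the donor); co-divergences and
        # duplications sit exactly at lca(s1, s2)
        if horiz[0] or horiz[1]:
            s_v = M[kids[1]] if horiz[0] else M[kids[0]]
            if s != s_v:
                return None
            ev = TRANSFER
        else:
            if s != index.lca(M[kids[0]], M[kids[1]]):
                return None
            if projs[0] & projs[1]:
                ev = DUPLICATION
            elif len(S.children(s)) == 2:
                ev = SPECIATION
            else:
                ev = COALESCENCE
        events[g] = ev
        sig[g] = projs[0] | projs[1]
        mode[g] = CODIV if ev in (SPECIATION, COALESCENCE) else EMIT
        for c, hz in zip(kids, horiz):
            recs = _oracle_losses(index, s, ev, sig[g], M[c], sig[c],
                                  mode[c], hz)
            if recs:
                losses[c] = recs
            if hz:
                transfers.append(TransferEdge(g, c, s, M[c]))

    n_d = sum(1 for e in events.values() if e == DUPLICATION)
    n_t = sum(1 for e in events.values() if e == TRANSFER)
    n_l = sum(len(r) for r in losses.values())
    score = 0.0
    if n_d:
        score += costs.dup * n_d
    if n_t:
        score += costs.trans * n_t
    if costs.losses_in_score and n_l:
        score += costs.loss * n_l
    return ReconciliationHistory(G, S, dict(M), events, losses,
                                 tuple(sorted(transfers)), score)


def _oracle_losses(index: SpeciesIndex, ps: int, pe: str,
                   psig: frozenset, cs: int, csig: frozenset, cmode: int,
                   horizontal: bool) -> tuple[LossRecord, ...]:
    recs: list[LossRecord] = []
    emit = pe in (DUPLICATION, TRANSFER)
    kids = index.tree.children(cs)
    charge = cmode != LEAF and bool(kids) and len(csig) < len(kids)
    if horizontal:
        pass
    elif cs == ps:
        charge = False
        if emit and cmode == CODIV:
            lost = tuple(sorted(psig - csig))
            if lost:
                recs.append(LossRecord(cs, lost))
    else:
        path = index.path_down(ps, cs)
        start = 0 if emit else 1
        for i in range(start, len(path) - 1):
            a, nxt = path[i], path[i + 1]
            if a == ps and emit:
                lost = tuple(sorted(psig - {nxt}))
            else:
                lost = tuple(sorted(c for c in index.tree.children(a)
                                    if c != nxt))
            if lost:
                recs.append(LossRecord(a, lost))
    if charge:
        recs.append(LossRecord(cs, tuple(sorted(set(kids) - csig))))
    return tuple(recs)


# ---------------------------------------------------------------------------
# random instances for the equivalence battery


def random_instance(seed: int):
    """A random small reconciliation instance: (gene tree, species tree,
    mapping, costs, model). Costs are dyadic rationals so that sums are
    exact in floating point regardless of association order; the model is
    drawn compatibly with the species-tree shape. Sized to fit the oracle
    guard."""
    rng = np.random.default_rng(seed)
    n_sp = int(rng.integers(3, 6))
    with_poly = bool(rng.random() < 0.5) and n_sp >= 3
    poly = int(rng.integers(3, n_sp + 1)) if with_poly else None
    labels = [chr(ord("A") + i) for i in range(n_sp)]
    sp = random_species_tree(n_sp, polytomy_size=poly,
                             seed=int(rng.integers(0, 2**31 - 1)),
                             labels=labels)
    has_poly = any(len(sp.children(i)) > 2 for i in sp.postorder())

    n_genes = int(rng.integers(2, 6))
    leaf_species = [labels[int(rng.integers(0, n_sp))]
                    for _ in range(n_genes)]
    items: list = [f"g{i}_{s}" for i, s in enumerate(leaf_species)]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        items.append(([a, b], None))
    gene = RootedTree.from_nested(items[0], GENE)
    mapping = leaf_mapping_from_suffix(gene, sp)

    grid = [0.25 * k for k in range(1, 25)]
    delta = float(rng.choice(grid))
    lam = float(rng.choice([0.0] + grid))
    tau = math.inf if rng.random() < 0.1 else float(rng.choice(grid))
    costs = CostScheme(trans=tau, dup=delta, loss=lam)
    models = ("DTI", "DTLI") if has_poly else ("DT", "DTI", "DTL", "DTLI")
    model = str(rng.choice(models))
    return gene, sp, mapping, costs, model


# ---------------------------------------------------------------------------
# temporal-feasibility oracle


def feasible_by_exhaustion(graph, limit: int = 8) -> bool:
    """Decide whether the constraint graph admits a consistent total order
    of its vertices: exhaustive permutation search for small graphs, a
    numpy boolean-matrix transitive closure otherwise. Independent of the
    topological-sort path used by the temporal module."""
    nodes = sorted(graph.nodes)
    edges = [(u, v) for u, v in graph.edges]
    if any(u == v for u, v in edges):
        return False
    if len(nodes) <= limit:
        for perm in itertools.permutations(nodes):
            pos = {v: i for i, v in enumerate(perm)}
            if all(pos[u] < pos[v] for u, v in edges):
                return True
        return False
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((n, n), dtype=bool)
    for u, v in edges:
        adj[idx[u], idx[v]] = True
    reach = adj.copy()
    for _ in range(n):
        newr = reach | (reach @ adj)
        if (newr == reach).all():
            break
        reach = newr
    return not bool(np.diag(reach).any())
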