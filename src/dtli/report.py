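"""Batch reconciliation, rooting by event parsimony, and transfer-highway
detection.

The batch protocol mirrors genome-scale survey practice: every gene tree
is reconciled under each model variant and transfer-cost setting; a tree
is excluded from a cell when it has no temporally feasible optimal
history (by default a tree failing anywhere is excluded everywhere), or
when its feasible optimal histories disagree in any event count
(degeneracy), since aggregate statistics from such trees would depend on
an arbitrary choice among optima. A transfer highway is a species pair
whose total bidirectional transfer count is an outlier -- here, exceeding
the mean pair count by more than 1.5 standard deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import CostScheme
from .reconcile import first_pass
from .solutions import (SolutionSet, second_pass, DEFAULT_MAX_SOLUTIONS)
from .temporal import filter_feasible
from .trees import (GENE, LeafMapping, RootedTree, SpeciesIndex,
                    build_species_index)

__all__ = [
    "enumerate_rootings", "RootSearchResult", "root_search",
    "TreeRecord", "CellStats", "BatchResult", "batch_reconcile",
    "TransferMatrix", "transfer_matrix", "detect_highways",
]


# ---------------------------------------------------------------------------
# rooting by event parsimony


def enumerate_rootings(tree: RootedTree) -> list[RootedTree]:
    """All rootings of the unrooted topology underlying a rooted binary
    gene tree: the (suppressed-root) tree re-rooted on each of its 2n-3
    edges, in deterministic order. The original rooting is among them."""
    leaves = tree.leaves()
    if len(leaves) == 2:
        return [tree.copy()]
    adj: dict[int, list[int]] = {i: [] for i in range(len(tree))}
    root_kids = tree.children(tree.root)
    for i in range(len(tree)):
        for c in tree.children(i):
            if i == tree.root:
                continue
            adj[i].append(c)
            adj[c].append(i)
    # suppress the (binary) root: connect its two children directly
    a, b = root_kids
    adj[a].append(b)
    adj[b].append(a)

    edges = sorted({tuple(sorted((u, v)))
                    for u in adj for v in adj[u]})

    def subtree(x: int, away: int):
        nbrs = [y for y in adj[x] if y != away]
        if not nbrs:
            return tree.label(x)
        return ([subtree(y, x) for y in nbrs], tree.label(x))

    out = []
    for u, v in edges:
        nested = ([subtree(u, v), subtree(v, u)], None)
        out.append(RootedTree.from_nested(nested, GENE))
    return out


@dataclass
class RootSearchResult:
    best_score: float
    entries: list  # (rooted tree, SolutionSet) per optimal root
    n_rootings: int


def root_search(gene_tree: RootedTree, species_tree: RootedTree,
                mapping: LeafMapping, costs: CostScheme,
                model: str = "DTLI",
                index: Optional[SpeciesIndex] = None,
                max_solutions: int = DEFAULT_MAX_SOLUTIONS,
                ) -> RootSearchResult:
    """Reconcile the gene tree rooted on every edge of its unrooted
    topology and return all rootings achieving the minimum score, each
    with its full solution set (ties are real and are all reported)."""
    if index is None:
        index = build_species_index(species_tree)
    label_map = {gene_tree.label(g): species_tree.label(s)
                 for g, s in mapping.items()}
    best = math.inf
    entries: list = []
    rootings = enumerate_rootings(gene_tree)
    for rt in rootings:
        m = LeafMapping({l: species_tree.leaf_id(label_map[rt.label(l)])
                         for l in rt.leaves()}, rt, species_tree)
        dp = first_pass(rt, species_tree, m, costs, model, index=index)
        if dp.optimal_score < best:
            best = dp.optimal_score
            entries = [(rt, dp)]
        elif dp.optimal_score == best:
            entries.append((rt, dp))
    resolved = [(rt, second_pass(dp, max_solutions=max_solutions))
                for rt, dp in entries]
    return RootSearchResult(best, resolved, len(rootings))


# ---------------------------------------------------------------------------
# batch protocol


@dataclass
class TreeRecord:
    """Per-tree, per-cell outcome."""

    name: str
    model: str
    tau: float
    score: Optional[float] = None
    n_optimal: Optional[int] = None
    n_feasible: Optional[int] = None
    status: str = "retained"       # retained | infeasible | degenerate | error
    counts: Optional[tuple] = None  # (n_D, n_T, n_L, n_C)
    transfer_pairs: list = field(default_factory=list)
    message: str = ""


@dataclass
class CellStats:
    """Aggregate of one (model, tau) cell over all input trees."""

    model: str
    tau: float
    n_D: int = 0
    n_T: int = 0
    n_L: int = 0
    n_C: int = 0
    retained: int = 0
    infeasible: int = 0
    degenerate: int = 0
    errors: int = 0
    records: list = field(default_factory=list)


@dataclass
class BatchResult:
    cells: dict  # (model, tau) -> CellStats
    n_trees: int
    species_trees: dict  # model -> RootedTree

    def to_table(self) -> pd.DataFrame:
        rows = []
        for (model, tau), c in sorted(self.cells.items()):
            rows.append({"model": model, "tau": tau, "n_D": c.n_D,
                         "n_T": c.n_T, "n_L": c.n_L, "n_C": c.n_C,
                         "retained": c.retained,
                         "infeasible": c.infeasible,
                         "degenerate": c.degenerate})
        return pd.DataFrame(rows)


def batch_reconcile(entries: Sequence[tuple],
                    species_tree: Union[RootedTree, dict],
                    taus: Sequence[float],
                    models: Sequence[str] = ("DT", "DTI", "DTL", "DTLI"),
                    dup: float = 3.0, loss: float = 2.0,
                    root_trees: bool = False,
                    cross_model_infeasible: bool = True,
                    max_solutions: int = DEFAULT_MAX_SOLUTIONS,
                    ) -> BatchResult:
    """Reconcile a collection of gene trees under every (model, tau) cell
    and aggregate event counts under the retention protocol.

    ``entries`` is a sequence of (name, gene_tree, mapping). A single
    species tree may be given, or a dict mapping model names to trees
    (models without ILS need a binary tree). With
    ``cross_model_infeasible`` (the default) a tree with no temporally
    feasible solution in any cell is excluded from every cell; degeneracy
    (feasible optima disagreeing in any event count) is assessed per
    cell. Per-tree failures are logged as error records, never fatal.
    """
    if isinstance(species_tree, dict):
        sp_by_model = dict(species_tree)
    else:
        sp_by_model = {m: species_tree for m in models}
    indexes = {m: build_species_index(sp_by_model[m]) for m in models}

    cellkeys = [(m, t) for m in models for t in taus]
    outcomes: dict[tuple, dict[str, TreeRecord]] = {k: {} for k in cellkeys}

    for name, gtree, mapping in entries:
        pairs = {gtree.label(g): None for g in gtree.leaves()}
        for model, tau in cellkeys:
            sp = sp_by_model[model]
            idx = indexes[model]
            costs = CostScheme(trans=tau, dup=dup, loss=loss)
            rec = TreeRecord(name, model, tau)
            try:
                feasible: list = []
                if root_trees:
                    rs = root_search(gtree, sp, _remap(mapping, gtree, sp),
                                     costs, model, index=idx,
                                     max_solutions=max_solutions)
                    rec.score = rs.best_score
                    rec.n_optimal = sum(ss.count for _, ss in rs.entries)
                    for _, ss in rs.entries:
                        filter_feasible(ss, idx)
                        feasible.extend(ss.feasible_histories())
                else:
                    dp = first_pass(gtree, sp, _remap(mapping, gtree, sp),
                                    costs, model, index=idx)
                    ss = second_pass(dp, max_solutions=max_solutions)
                    filter_feasible(ss, idx)
                    rec.score = dp.optimal_score
                    rec.n_optimal = ss.count
                    feasible = ss.feasible_histories()
                rec.n_feasible = len(feasible)
                if not feasible:
                    rec.status = "infeasible"
                elif len({h.counts() for h in feasible}) > 1:
                    rec.status = "degenerate"
                else:
                    rec.status = "retained"
                    rec.counts = feasible[0].counts()
                    spx = sp_by_model[model]
                    rec.transfer_pairs = [
                        (spx.display_label(t.donor),
                         spx.display_label(t.recipient))
                        for t in feasible[0].transfers]
            except Exception as exc:  # per-tree failures logged, not fatal
                rec.status = "error"
                rec.message = str(exc)
            outcomes[(model, tau)][name] = rec

    if cross_model_infeasible:
        bad = {name for cell in outcomes.values()
               for name, rec in cell.items() if rec.status == "infeasible"}
        for cell in outcomes.values():
            for name, rec in cell.items():
                if name in bad and rec.status in ("retained", "degenerate"):
                    rec.status = "infeasible"
                    rec.counts = None
                    rec.transfer_pairs = []

    cells = {}
    n_trees = len(entries)
    for key in cellkeys:
        model, tau = key
        c = CellStats(model, tau)
        for name, _g, _m in [(e[0], e[1], e[2]) for e in entries]:
            rec = outcomes[key][name]
            c.records.append(rec)
            if rec.status == "retained":
                c.retained += 1
                c.n_D += rec.counts[0]
                c.n_T += rec.counts[1]
                c.n_L += rec.counts[2]
                c.n_C += rec.counts[3]
            elif rec.status == "infeasible":
                c.infeasible += 1
            elif rec.status == "degenerate":
                c.degenerate += 1
            else:
                c.errors += 1
        cells[key] = c
    return BatchResult(cells, n_trees, sp_by_model)


def _remap(mapping: LeafMapping, gtree: RootedTree,
           sp: RootedTree) -> LeafMapping:
    """Rebind a label-level mapping to a possibly different species-tree
    object (batch cells may use different trees per model)."""
    if mapping.species_tree is sp and mapping.gene_tree is gtree:
        return mapping
    pairs = {g: sp.leaf_id(mapping.species_tree.label(s))
             for g, s in mapping.items()}
    return LeafMapping(pairs, gtree, sp)


# ---------------------------------------------------------------------------
# transfer matrix and highways


@dataclass
class TransferMatrix:
    """Symmetric species-pair transfer totals. The pair universe is every
    unordered pair of non-root species nodes that could in principle
    exchange genes (phylogenetically incomparable pairs), keyed by node
    labels; zero counts are kept so outlier statistics are computed over
    the whole universe."""

    counts: dict  # frozenset({label_a, label_b}) -> int
    labels: list

    def pair_items(self) -> list[tuple[tuple[str, str], int]]:
        return sorted(((tuple(sorted(k)), v) for k, v in
                       self.counts.items()))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"species_a": a, "species_b": b, "transfers": v}
                for (a, b), v in self.pair_items()]
        return pd.DataFrame(rows)


def transfer_matrix(batch: BatchResult, model: str,
                    tau: float) -> TransferMatrix:
    """Total transfers between each species pair, both directions folded
    together, summed over the retained trees of one (model, tau) cell.
    Ancestral-lineage donors/recipients are included, keyed by their
    node labels."""
    sp = batch.species_trees[model]
    index = build_species_index(sp, force=True)
    counts: dict[frozenset, int] = {}
    labels = []
    for u in range(len(sp)):
        if sp.parent(u) is None:
            continue
        labels.append(sp.display_label(u))
        for v in range(u + 1, len(sp)):
            if sp.parent(v) is None:
                continue
            if index.incomparable(u, v):
                counts[frozenset((sp.display_label(u),
                                  sp.display_label(v)))] = 0
    cell = batch.cells[(model, tau)]
    for rec in cell.records:
        if rec.status != "retained":
            continue
        for d, r in rec.transfer_pairs:
            key = frozenset((d, r))
            counts[key] = counts.get(key, 0) + 1
    return TransferMatrix(counts, labels)


def detect_highways(matrix: TransferMatrix,
                    multiplier: float = 1.5
                    ) -> list[tuple[tuple[str, str], int]]:
    """Species pairs whose transfer count strictly exceeds
    mean + multiplier * SD of all pair counts (population SD over the
    whole pair universe, zeros included)."""
    items = matrix.pair_items()
    if len(items) < 2:
        raise ValueError("need at least 2 species pairs for outlier "
                         "statistics")
    values = np.array([v for _, v in items], dtype=float)
    threshold = values.mean() + multiplier * values.std()
    return [(pair, int(v)) for pair, v in items if v > threshold]
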