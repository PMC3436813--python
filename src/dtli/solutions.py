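"""The secondPass traceback: enumerate every optimal history, materialize
fully annotated reconciled trees, rescore them independently, and detect
degeneracy among optimal solutions.

A history annotates every internal gene node with its species M(g) and
event (duplication, transfer, speciation, coalescence), every gene edge
with its loss records, and carries the set of transfer edges with donor
and recipient species. Two histories are the same iff node maps, events,
transfer edges and canonical loss labels all coincide; the traceback
emits each exactly once, in a deterministic order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Optional

from .model import COALESCENCE, DUPLICATION, TRANSFER, CostScheme
from .reconcile import DPResult, Key, count_losses
from .trees import RootedTree

__all__ = [
    "TransferEdge", "ReconciliationHistory", "SolutionSet", "EventCounts",
    "second_pass", "score_history", "summarize_events",
    "write_annotated_tree", "read_annotated_counts",
]

DEFAULT_MAX_SOLUTIONS = 10_000


class TransferEdge(NamedTuple):
    """A horizontal gene edge: (parent gene node, child gene node, donor
    species, recipient species)."""

    gene_parent: int
    gene_child: int
    donor: int
    recipient: int


@dataclass
class ReconciliationHistory:
    """One complete annotated reconciliation of a gene tree."""

    gene_tree: RootedTree
    species_tree: RootedTree
    mapping: dict          # gene node id -> species node id (all nodes)
    events: dict           # internal gene node id -> event label
    losses: dict           # gene child node id -> tuple[LossRecord, ...]
    transfers: tuple       # tuple[TransferEdge, ...]
    score: float
    feasible: Optional[bool] = None

    def counts(self) -> tuple[int, int, int, int]:
        """(n_D, n_T, n_L, n_C)."""
        n_d = sum(1 for e in self.events.values() if e == DUPLICATION)
        n_t = sum(1 for e in self.events.values() if e == TRANSFER)
        n_c = sum(1 for e in self.events.values() if e == COALESCENCE)
        n_l = sum(len(r) for r in self.losses.values())
        return (n_d, n_t, n_l, n_c)

    def n_losses(self) -> int:
        return sum(len(r) for r in self.losses.values())

    def canonical(self):
        """Hashable identity: node map, events, transfer edges and the
        canonical loss labels."""
        return (
            tuple(sorted(self.mapping.items())),
            tuple(sorted(self.events.items())),
            tuple(sorted(self.transfers)),
            tuple(sorted((g, rec.species, rec.lost)
                         for g, recs in self.losses.items()
                         for rec in recs)),
        )


@dataclass
class SolutionSet:
    """All optimal histories of one reconciliation instance.

    ``count`` is the exact number of optimal histories from the DP;
    ``histories`` holds the enumerated ones (all of them unless
    ``truncated``). ``status`` is set by the temporal filter.
    """

    score: float
    histories: list
    count: int
    truncated: bool = False
    status: Optional[str] = None

    @property
    def degenerate(self) -> bool:
        """True iff at least two optimal histories disagree in any event
        count (the retention rule for aggregate analyses)."""
        cs = {h.counts() for h in self.histories}
        return len(cs) > 1

    def feasible_histories(self) -> list:
        return [h for h in self.histories if h.feasible]

    @property
    def feasible_count(self) -> Optional[int]:
        if any(h.feasible is None for h in self.histories):
            return None
        return sum(1 for h in self.histories if h.feasible)


def second_pass(dp: DPResult,
                max_solutions: int = DEFAULT_MAX_SOLUTIONS) -> SolutionSet:
    """Enumerate every optimal history from the filled DP tables.

    Traverses, in pre-order of the gene tree, each unique path through the
    history tables that leads to an optimal root label. Each history is
    independently rescored from its annotations; a mismatch with the DP
    optimum indicates corrupted tables and raises.
    """
    G = dp.gene_tree
    tables = dp.tables
    index = dp.index

    def expand(g: int, key: Key) -> Iterator[dict]:
        entry = tables[g].get(key)
        if entry is None:
            raise RuntimeError(
                f"internal consistency error: no candidate stored at gene "
                f"node {g} for key {key}")
        if G.is_leaf(g):
            yield {g: (key, None)}
            return
        c1, c2 = G.children(g)
        for cand in entry.candidates:
            (k1, _h1), (k2, _h2) = cand.children
            for a1 in expand(c1, k1):
                for a2 in expand(c2, k2):
                    out = {g: (key, cand)}
                    out.update(a1)
                    out.update(a2)
                    yield out

    histories: list[ReconciliationHistory] = []
    truncated = False
    for root_key in dp.optimal_root_keys:
        if truncated:
            break
        for assignment in expand(G.root, root_key):
            if len(histories) >= max_solutions:
                truncated = True
                break
            histories.append(_materialize(dp, assignment))

    for h in histories:
        if score_history(h, dp.costs) != dp.optimal_score:
            raise RuntimeError(
                "internal consistency error: traceback history rescored "
                f"{score_history(h, dp.costs)} != DP optimum "
                f"{dp.optimal_score}")
    return SolutionSet(dp.optimal_score, histories, dp.num_optimal,
                       truncated=truncated)


def _materialize(dp: DPResult, assignment: dict) -> ReconciliationHistory:
    G = dp.gene_tree
    index = dp.index
    mapping: dict[int, int] = {}
    events: dict[int, str] = {}
    losses: dict[int, tuple] = {}
    transfers: list[TransferEdge] = []
    for g, (key, cand) in assignment.items():
        mapping[g] = key[0]
        if cand is None:
            continue
        events[g] = cand.event
        for child, (ckey, horiz) in zip(G.children(g), cand.children):
            recs = count_losses(key[0], cand.event, key[1], ckey[0],
                                ckey[1], ckey[2], horiz, index)
            if recs:
                losses[child] = recs
            if horiz:
                transfers.append(TransferEdge(g, child, key[0], ckey[0]))
    hist = ReconciliationHistory(
        G, dp.species_tree, mapping, events, losses,
        tuple(sorted(transfers)), 0.0)
    hist.score = score_history(hist, dp.costs)
    return hist


def score_history(history: ReconciliationHistory,
                  costs: CostScheme) -> float:
    """Rescore a history purely from its annotations: the weighted event
    sum, with the loss term dropped when losses are excluded from the
    optimization criterion."""
    n_d, n_t, n_l, _ = history.counts()
    # terms are added only for nonzero counts so that an infinite event
    # cost (the transfer-free sentinel) never produces inf * 0 = nan
    total = 0.0
    if n_d:
        total += costs.dup * n_d
    if n_t:
        total += costs.trans * n_t
    if costs.losses_in_score and n_l:
        total += costs.loss * n_l
    return total


@dataclass
class EventCounts:
    """Aggregate event statistics over a solution set. ``n_D``..``n_C``
    are the first history's counts (shared by all histories when not
    degenerate); the tallies sum over every enumerated history."""

    n_D: int
    n_T: int
    n_L: int
    n_C: int
    degenerate: bool
    per_history: list
    species_tallies: dict = field(default_factory=dict)
    transfer_tallies: dict = field(default_factory=dict)


def summarize_events(solutions: SolutionSet) -> EventCounts:
    """Tabulate events per history, flag count degeneracy, and tally the
    species lineages involved (per event type, and per donor/recipient
    pair for transfers)."""
    if not solutions.histories:
        raise ValueError("empty solution set")
    per = [h.counts() for h in solutions.histories]
    species_tallies: dict[tuple[str, str], int] = {}
    transfer_tallies: dict[tuple[str, str], int] = {}
    for h in solutions.histories:
        sp = h.species_tree
        for g, ev in h.events.items():
            lab = sp.display_label(h.mapping[g])
            species_tallies[(lab, ev)] = species_tallies.get(
                (lab, ev), 0) + 1
        for t in h.transfers:
            pair = (sp.display_label(t.donor), sp.display_label(t.recipient))
            transfer_tallies[pair] = transfer_tallies.get(pair, 0) + 1
    n_d, n_t, n_l, n_c = per[0]
    return EventCounts(n_d, n_t, n_l, n_c, len(set(per)) > 1, per,
                       species_tallies, transfer_tallies)


# -- annotated output --------------------------------------------------------


def _nhx_escape(s: str) -> str:
    return s.replace(":", "_").replace("=", "_").replace("]", "_")


def write_annotated_tree(history: ReconciliationHistory
                         ) -> tuple[str, str]:
    """Render a history as (NHX-annotated Newick, TSV event table).

    NHX tags: ``S`` the species assignment, ``Ev`` the event code
    (D/T/S/C) at internal nodes, ``Hor=Y`` with ``Don``/``Rec`` on the
    child node of each transfer edge, and ``Loss`` records
    (``species~lostchild+lostchild`` joined by ``|``) on the edge above a
    node. Output is bit-stable for a fixed history.
    """
    G = history.gene_tree
    sp = history.species_tree
    horizontal = {t.gene_child: t for t in history.transfers}

    def tag(i: int) -> str:
        parts = [f"S={_nhx_escape(sp.display_label(history.mapping[i]))}"]
        if i in history.events:
            parts.append(f"Ev={history.events[i]}")
        t = horizontal.get(i)
        if t is not None:
            parts.append("Hor=Y")
            parts.append(f"Don={_nhx_escape(sp.display_label(t.donor))}")
            parts.append(f"Rec={_nhx_escape(sp.display_label(t.recipient))}")
        recs = history.losses.get(i, ())
        if recs:
            enc = "|".join(
                _nhx_escape(sp.display_label(r.species)) + "~" +
                "+".join(_nhx_escape(sp.display_label(c)) for c in r.lost)
                for r in recs)
            parts.append(f"Loss={enc}")
        return "[&&NHX:" + ":".join(parts) + "]"

    def rec(i: int) -> str:
        nd = G.nodes[i]
        if nd.is_leaf:
            return nd.label + tag(i)
        inner = ",".join(rec(c) for c in nd.children)
        return f"({inner}){G.display_label(i)}{tag(i)}"

    nhx = rec(G.root) + ";"

    rows = ["type\tgene_node\tspecies\tdonor\trecipient\tloss_clade"]
    for g in sorted(history.events):
        ev = history.events[g]
        t = next((t for t in history.transfers if t.gene_parent == g), None)
        rows.append("\t".join([
            ev, G.display_label(g), sp.display_label(history.mapping[g]),
            sp.display_label(t.donor) if t else "",
            sp.display_label(t.recipient) if t else "", ""]))
    for g in sorted(history.losses):
        for r in history.losses[g]:
            clade = "{" + ",".join(sp.display_label(c) for c in r.lost) + "}"
            rows.append("\t".join([
                "L", G.display_label(g), sp.display_label(r.species),
                "", "", clade]))
    return nhx, "\n".join(rows) + "\n"


def read_annotated_counts(nhx_text: str) -> EventCounts:
    """Parse an NHX string produced by :func:`write_annotated_tree` back
    into event counts and tallies (round-trip check support)."""
    import re

    per_event: dict[str, int] = {"D": 0, "T": 0, "S": 0, "C": 0}
    species_tallies: dict[tuple[str, str], int] = {}
    transfer_tallies: dict[tuple[str, str], int] = {}
    n_l = 0
    for m in re.finditer(r"\[&&NHX:([^\]]*)\]", nhx_text):
        fields = dict(p.split("=", 1) for p in m.group(1).split(":"))
        ev = fields.get("Ev")
        if ev:
            per_event[ev] += 1
            species_tallies[(fields["S"], ev)] = species_tallies.get(
                (fields["S"], ev), 0) + 1
        if fields.get("Hor") == "Y":
            pair = (fields["Don"], fields["Rec"])
            transfer_tallies[pair] = transfer_tallies.get(pair, 0) + 1
        loss = fields.get("Loss")
        if loss:
            n_l += len(loss.split("|"))
    return EventCounts(per_event["D"], per_event["T"], n_l, per_event["C"],
                       False, [], species_tallies, transfer_tallies)
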