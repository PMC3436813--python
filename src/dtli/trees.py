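"""Rooted trees, species-tree indexing and leaf mappings.

Trees are stored with stable integer node ids assigned in a deterministic
post-order (children in input order), so that every downstream output --
DP tables, history enumeration order, annotated Newick -- is reproducible
across runs for the same input text.

Newick parsing is delegated to dendropy; the algorithm itself is
topology-only, so branch lengths and comments are parsed and discarded.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = [
    "TreeError",
    "MappingError",
    "Node",
    "RootedTree",
    "SpeciesIndex",
    "LeafMapping",
    "parse_newick",
    "write_newick",
    "build_species_index",
    "read_leaf_mapping",
    "leaf_mapping_from_suffix",
    "collapse_edge",
]

GENE = "gene"
SPECIES = "species"

#: Refuse to enumerate child subsets for polytomies larger than this unless
#: the caller forces it: the DP key space grows as 2^outdegree per polytomy.
MAX_POLYTOMY = 12


class TreeError(ValueError):
    """Malformed tree text or a violated tree-role invariant."""


class MappingError(ValueError):
    """Invalid or incomplete gene-leaf -> species-leaf mapping."""


class Node:
    """A tree node: id, optional label, parent id (None at the root),
    ordered child ids."""

    __slots__ = ("id", "label", "parent", "children")

    def __init__(self, id: int, label: Optional[str], parent: Optional[int],
                 children: tuple[int, ...]):
        self.id = id
        self.label = label
        self.parent = parent
        self.children = children

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.id}, {self.label!r})"


class RootedTree:
    """A rooted, node-labeled tree with post-order integer ids.

    ``role`` is ``"gene"`` (every internal node binary) or ``"species"``
    (internal nodes of out-degree >= 2, polytomies allowed).
    """

    def __init__(self, nodes: list[Node], root: int, role: str):
        self.nodes = nodes
        self.root = root
        self.role = role
        self._leaf_by_label: dict[str, int] = {}
        for nd in nodes:
            if nd.is_leaf:
                if nd.label is None:
                    raise TreeError("unlabeled leaf")
                if nd.label in self._leaf_by_label:
                    raise TreeError(f"duplicate leaf label {nd.label!r}")
                self._leaf_by_label[nd.label] = nd.id
        self._validate()

    # -- construction ---------------------------------------------------

    @classmethod
    def from_nested(cls, nested, role: str) -> "RootedTree":
        """Build from nested structure: a leaf is a ``str`` label, an
        internal node is ``(children_list, label_or_None)``."""
        nodes: list[Node] = []

        def build(item, parent_placeholder=None) -> int:
            if isinstance(item, str):
                nodes.append(Node(len(nodes), item, None, ()))
                return nodes[-1].id
            children, label = item
            child_ids = [build(c) for c in children]
            nid = len(nodes)
            nodes.append(Node(nid, label, None, tuple(child_ids)))
            for c in child_ids:
                nodes[c].parent = nid
            return nid

        root = build(nested)
        return cls(nodes, root, role)

    def _validate(self) -> None:
        if self.role not in (GENE, SPECIES):
            raise TreeError(f"unknown tree role {self.role!r}")
        seen_root = False
        for nd in self.nodes:
            if nd.parent is None:
                if nd.id != self.root:
                    raise TreeError("multiple roots")
                seen_root = True
            if not nd.is_leaf:
                if self.role == GENE and len(nd.children) != 2:
                    raise TreeError(
                        f"gene tree must be binary; node {nd.id} "
                        f"({nd.label or 'unlabeled'}) has "
                        f"{len(nd.children)} children")
                if len(nd.children) < 2:
                    raise TreeError(
                        f"internal node {nd.id} has out-degree "
                        f"{len(nd.children)} (< 2)")
        if not seen_root:
            raise TreeError("no root")

    # -- basic queries ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, i: int) -> Node:
        return self.nodes[i]

    def children(self, i: int) -> tuple[int, ...]:
        return self.nodes[i].children

    def parent(self, i: int) -> Optional[int]:
        return self.nodes[i].parent

    def is_leaf(self, i: int) -> bool:
        return self.nodes[i].is_leaf

    def label(self, i: int) -> Optional[str]:
        return self.nodes[i].label

    def leaves(self) -> list[int]:
        return [nd.id for nd in self.nodes if nd.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [nd.label for nd in self.nodes if nd.is_leaf]

    def leaf_id(self, label: str) -> int:
        try:
            return self._leaf_by_label[label]
        except KeyError:
            raise MappingError(f"no leaf labeled {label!r}") from None

    def has_leaf(self, label: str) -> bool:
        return label in self._leaf_by_label

    def postorder(self) -> Iterator[int]:
        """Node ids in post-order (== ascending id order by construction)."""
        return iter(range(len(self.nodes)))

    def preorder(self) -> Iterator[int]:
        stack = [self.root]
        while stack:
            i = stack.pop()
            yield i
            stack.extend(reversed(self.nodes[i].children))

    def display_label(self, i: int) -> str:
        """Node label, or a stable synthetic name for unlabeled internals."""
        lab = self.nodes[i].label
        return lab if lab is not None else f"n{i}"

    # -- structure edits (functional) -------------------------------------

    def _nested(self, i: int):
        nd = self.nodes[i]
        if nd.is_leaf:
            return nd.label
        return ([self._nested(c) for c in nd.children], nd.label)

    def copy(self) -> "RootedTree":
        return RootedTree.from_nested(self._nested(self.root), self.role)

    def cluster_set(self) -> set[frozenset[str]]:
        """The set of leaf-label clusters, one per internal node."""
        below: dict[int, frozenset[str]] = {}
        for i in self.postorder():
            nd = self.nodes[i]
            if nd.is_leaf:
                below[i] = frozenset([nd.label])
            else:
                below[i] = frozenset().union(*(below[c] for c in nd.children))
        return {below[nd.id] for nd in self.nodes if not nd.is_leaf}


def parse_newick(text: str, role: str) -> RootedTree:
    """Parse a Newick string into a RootedTree with the given role.

    Internal labels and quoted labels are kept; branch lengths and
    comments are parsed but discarded. A non-binary internal node in a
    gene tree is a validation error.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=False)
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed Newick: {exc}") from exc

    def conv(dnode):
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        if dnode.is_leaf():
            if label is None:
                raise TreeError("unlabeled leaf in Newick input")
            return label
        return ([conv(c) for c in dnode.child_nodes()], label)

    root = dtree.seed_node
    # dendropy tolerates a degree-1 "root" wrapper; unwrap it.
    while len(root.child_nodes()) == 1:
        root = root.child_nodes()[0]
    if root.is_leaf():
        raise TreeError("tree has fewer than 2 leaves")
    return RootedTree.from_nested(conv(root), role)


def _quote(label: str) -> str:
    if any(ch in label for ch in "()[]{}:;,' \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: RootedTree) -> str:
    """Write a Newick string (labels only; no branch lengths)."""

    def rec(i: int) -> str:
        nd = tree.nodes[i]
        if nd.is_leaf:
            return _quote(nd.label)
        inner = ",".join(rec(c) for c in nd.children)
        lab = _quote(nd.label) if nd.label is not None else ""
        return f"({inner}){lab}"

    return rec(tree.root) + ";"


def collapse_edge(tree: RootedTree, child_id: int) -> RootedTree:
    """Collapse the internal edge above ``child_id``: remove the child node
    and promote its children to its parent, creating or growing a polytomy.
    Returns a new tree; the leaf set is unchanged."""
    nd = tree.nodes[child_id]
    if nd.is_leaf:
        raise TreeError("cannot collapse a leaf edge")
    if nd.parent is None:
        raise TreeError("cannot collapse the root (it has no parent edge)")

    def rec(i: int):
        n = tree.nodes[i]
        if n.is_leaf:
            return n.label
        kids = []
        for c in n.children:
            if c == child_id:
                kids.extend(rec(gc) for gc in tree.nodes[c].children)
            else:
                kids.append(rec(c))
        return (kids, n.label)

    return RootedTree.from_nested(rec(tree.root), tree.role)


class SpeciesIndex:
    """Precomputed ancestry machinery for a species tree.

    Provides all-pairs lca, the ancestor-or-equal relation, the
    incomparability predicate, per-node depth, the child of an ancestor
    lying toward a given descendant, and cached enumeration of the
    nonempty child subsets C(s)^+ used as DP keys at polytomies.
    """

    def __init__(self, tree: RootedTree, force: bool = False):
        if tree.role != SPECIES:
            raise TreeError("SpeciesIndex requires a species tree")
        self.tree = tree
        n = len(tree)
        self.n = n
        self.depth = [0] * n
        order = list(tree.preorder())
        for i in order:
            p = tree.parent(i)
            self.depth[i] = 0 if p is None else self.depth[p] + 1
        self.height = max(self.depth[l] for l in tree.leaves())
        degs = [len(tree.children(i)) for i in range(n)
                if not tree.is_leaf(i)]
        self.k_star = max(degs) if degs else 0
        self.n_polytomies = sum(1 for d in degs if d > 2)
        if self.k_star > MAX_POLYTOMY and not force:
            raise TreeError(
                f"species tree has a polytomy of out-degree {self.k_star} "
                f"(> {MAX_POLYTOMY}); subset enumeration is exponential -- "
                f"pass force=True to proceed anyway")

        # ancestor-or-equal sets as python int bitmasks over node ids
        anc = [0] * n  # anc[v] = bitmask of ancestors-or-equal of v
        for i in order:
            p = tree.parent(i)
            anc[i] = (1 << i) if p is None else anc[p] | (1 << i)
        self._ancmask = anc

        # all-pairs lca: deepest common node on the two root paths
        self._lca = [[0] * n for _ in range(n)]
        paths = []
        for v in range(n):
            path = []
            u = v
            while u is not None:
                path.append(u)
                u = tree.parent(u)
            paths.append(set(path))
        for u in range(n):
            for v in range(n):
                w = u
                while w not in paths[v]:
                    w = tree.parent(w)
                self._lca[u][v] = w

        self._subsets: dict[int, tuple[frozenset[int], ...]] = {}

    # -- predicates -------------------------------------------------------

    def is_ancestor(self, u: int, v: int) -> bool:
        """u >=_S v (ancestor-or-equal)."""
        return bool(self._ancmask[v] & (1 << u))

    def is_strict_ancestor(self, u: int, v: int) -> bool:
        return u != v and self.is_ancestor(u, v)

    def incomparable(self, u: int, v: int) -> bool:
        return not (self.is_ancestor(u, v) or self.is_ancestor(v, u))

    def lca(self, u: int, v: int) -> int:
        return self._lca[u][v]

    def child_toward(self, a: int, d: int) -> int:
        """The child of ``a`` that is an ancestor-or-equal of ``d``
        (requires a >_S d)."""
        for c in self.tree.children(a):
            if self.is_ancestor(c, d):
                return c
        raise ValueError(f"{d} is not a proper descendant of {a}")

    def path_down(self, a: int, d: int) -> list[int]:
        """Nodes from ``a`` down to ``d`` inclusive (a >=_S d)."""
        rev = []
        u = d
        while u != a:
            rev.append(u)
            u = self.tree.parent(u)
        rev.append(a)
        return rev[::-1]

    def subsets(self, s: int) -> tuple[frozenset[int], ...]:
        """The nonempty subsets of C(s), lazily enumerated and cached;
        2^|C(s)| - 1 of them, in deterministic order."""
        cached = self._subsets.get(s)
        if cached is not None:
            return cached
        kids = self.tree.children(s)
        out = []
        for mask in range(1, 1 << len(kids)):
            out.append(frozenset(kids[j] for j in range(len(kids))
                                 if mask & (1 << j)))
        self._subsets[s] = tuple(out)
        return self._subsets[s]


def build_species_index(tree: RootedTree, force: bool = False) -> SpeciesIndex:
    """Build the ancestry index for a species tree (see SpeciesIndex)."""
    return SpeciesIndex(tree, force=force)


class LeafMapping:
    """Total function from gene-tree leaves to species-tree leaves.

    Need not be injective (paralogs) nor surjective (unsampled species).
    """

    def __init__(self, pairs: dict[int, int], gene_tree: RootedTree,
                 species_tree: RootedTree):
        missing = [gene_tree.label(l) for l in gene_tree.leaves()
                   if l not in pairs]
        if missing:
            raise MappingError(
                f"gene leaves without a species mapping: {sorted(missing)}")
        self.map = dict(pairs)
        self.gene_tree = gene_tree
        self.species_tree = species_tree

    def __getitem__(self, gene_leaf: int) -> int:
        return self.map[gene_leaf]

    def items(self):
        return self.map.items()

    def as_label_pairs(self) -> list[tuple[str, str]]:
        return sorted(
            (self.gene_tree.label(g), self.species_tree.label(s))
            for g, s in self.map.items())


def read_leaf_mapping(source, gene_tree: RootedTree,
                      species_tree: RootedTree) -> LeafMapping:
    """Read a two-column TSV (gene leaf, species leaf) into a LeafMapping.

    ``source`` may be a path, a file-like object, or an iterable of lines.
    Unknown species names and gene leaves left unmapped are errors.
    """
    if isinstance(source, str) and "\t" not in source and "\n" not in source:
        fh: Iterable[str] = open(source)
    elif isinstance(source, str):
        fh = io.StringIO(source)
    elif hasattr(source, "read"):
        fh = source
    else:
        fh = source
    pairs: dict[int, int] = {}
    for lineno, line in enumerate(fh, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise MappingError(
                f"line {lineno}: expected 2 tab-separated columns, "
                f"got {len(fields)}")
        gname, sname = fields
        if not gene_tree.has_leaf(gname):
            raise MappingError(f"line {lineno}: unknown gene leaf {gname!r}")
        if not species_tree.has_leaf(sname):
            raise MappingError(
                f"line {lineno}: species {sname!r} absent from species tree")
        pairs[gene_tree.leaf_id(gname)] = species_tree.leaf_id(sname)
    return LeafMapping(pairs, gene_tree, species_tree)


def leaf_mapping_from_suffix(gene_tree: RootedTree,
                             species_tree: RootedTree,
                             sep: str = "_") -> LeafMapping:
    """Build a mapping from the GENE_SPECIES leaf-name convention: the
    species name is the part of the gene-leaf label after the last ``sep``."""
    pairs: dict[int, int] = {}
    for l in gene_tree.leaves():
        label = gene_tree.label(l)
        if sep not in label:
            raise MappingError(
                f"gene leaf {label!r} has no {sep!r} species suffix")
        sname = label.rsplit(sep, 1)[1]
        if not species_tree.has_leaf(sname):
            raise MappingError(
                f"gene leaf {label!r}: species {sname!r} not in species tree")
        pairs[l] = species_tree.leaf_id(sname)
    return LeafMapping(pairs, gene_tree, species_tree)
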