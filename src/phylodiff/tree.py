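"""Phylogenetic tree structure, Newick I/O, rooting, and path distances.

Trees are stored as recursive :class:`Clade` nodes (name, branch length to
the parent, optional bootstrap support on that branch, children).  An
unrooted tree is represented rooted at an arbitrary internal node of
degree >= 3, with ``PhyloTree.rooted = False``; a rooted tree has a root
of degree >= 2 (typically the midpoint of the outgroup's pendant edge).

Newick serialization is written here; parsing is delegated to dendropy.
Internal node labels are interpreted as bootstrap support values when they
parse as numbers, which is the common convention for consensus trees.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceMatrix

__all__ = [
    "Clade",
    "NewickError",
    "PhyloTree",
    "from_newick",
    "path_distance_matrix",
    "root_with_outgroup",
]


class NewickError(ValueError):
    """Raised on malformed Newick input."""


@dataclass
class Clade:
    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class PhyloTree:
    root: Clade
    rooted: bool = False

    def leaves(self) -> list[Clade]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find_leaf(self, name: str) -> Clade:
        for n in self.leaves():
            if n.name == name:
                return n
        raise KeyError(f"no leaf named {name!r}")

    def copy(self) -> "PhyloTree":
        return PhyloTree(_copy.deepcopy(self.root), self.rooted)

    def bipartitions(self, with_support: bool = False):
        """Nontrivial splits as frozensets oriented away from the smallest leaf.

        Returns ``{split: support}`` if ``with_support`` else a set of splits.
        """
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out: dict[frozenset, float | None] = {}

        def _collect(node: Clade) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(_collect(c) for c in node.children))
            side = below if ref not in below else all_leaves - below
            if 2 <= len(side) <= len(all_leaves) - 2:
                out[side] = node.support
            return below

        for child in self.root.children:
            _collect(child)
        return out if with_support else set(out)

    def to_newick(
        self,
        lengths: bool = True,
        supports: bool = False,
        precision: int = 6,
    ) -> str:
        def fmt_len(node: Clade) -> str:
            if not lengths or node.length is None:
                return ""
            return f":{node.length:.{precision}g}"

        def fmt(node: Clade) -> str:
            if node.is_leaf:
                return _escape(node.name or "") + fmt_len(node)
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if supports and node.support is not None:
                label = f"{node.support:g}"
            elif node.name:
                label = _escape(node.name)
            return f"({inner}){label}{fmt_len(node)}"

        return fmt(self.root) + ";"

    def canonical_newick(self) -> str:
        """Topology-only Newick that is invariant to child order and, for
        unrooted trees, to the internal node chosen as the anchor."""
        tree = self
        if not self.rooted:
            tree = root_with_outgroup(self, min(self.leaf_names()))

        def key(node: Clade) -> str:
            if node.is_leaf:
                return _escape(node.name or "")
            parts = sorted(key(c) for c in node.children)
            return "(" + ",".join(parts) + ")"

        return key(tree.root) + ";"


def _escape(name: str) -> str:
    if any(ch in name for ch in "(),:;'[] \t"):
        return "'" + name.replace("'", "''") + "'"
    return name


# ---------------------------------------------------------------------------
# Newick parsing (via dendropy)


def from_newick(text: str, rooted: bool | None = None) -> PhyloTree:
    """Parse a Newick string; numeric internal labels become branch supports.

    ``rooted=None`` infers the flag: a bifurcating top-level node is taken
    as a root, a trifurcation (or higher) as an unrooted anchor.
    """
    import dendropy

    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise NewickError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Clade:
        clade = Clade(length=dnode.edge.length)
        if dnode.taxon is not None:
            clade.name = dnode.taxon.label
        elif dnode.label is not None:
            try:
                clade.support = float(dnode.label)
            except ValueError:
                clade.name = dnode.label
        clade.children = [convert(c) for c in dnode.child_nodes()]
        return clade

    root = convert(dtree.seed_node)
    if not root.children:
        raise NewickError("Newick tree has no children at the top level")
    if rooted is None:
        rooted = len(root.children) == 2
    return PhyloTree(root, rooted)


# ---------------------------------------------------------------------------
# Path distances


def path_distance_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix d^T (branch lengths summed).

    Missing branch lengths are treated as zero. Labels are sorted for
    determinism.
    """
    adj = _adjacency(tree.root)
    leaves = sorted(n.name for n in tree.root.walk() if n.is_leaf)
    name_to_node = {n.name: n for n in tree.root.walk() if n.is_leaf}
    n = len(leaves)
    values = np.zeros((n, n))
    for i, name in enumerate(leaves):
        dist = _dijkstra_like(adj, name_to_node[name])
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = dist[id(name_to_node[leaves[j]])]
    return DistanceMatrix(leaves, values)


def _adjacency(root: Clade):
    """Undirected adjacency: id(node) -> list of (neighbor, length, child_node).

    ``child_node`` is the clade that carries the edge's length/support
    attributes (always the child in the stored orientation).
    """
    adj: dict[int, list] = {}
    nodes: dict[int, Clade] = {}

    def visit(node: Clade):
        nodes[id(node)] = node
        adj.setdefault(id(node), [])
        for c in node.children:
            visit(c)
            length = c.length if c.length is not None else 0.0
            adj[id(node)].append((c, length))
            adj[id(c)].append((node, length))

    visit(root)
    return adj


def _dijkstra_like(adj, start: Clade) -> dict[int, float]:
    dist = {id(start): 0.0}
    stack = [start]
    while stack:
        node = stack.pop()
        for nbr, length in adj[id(node)]:
            if id(nbr) not in dist:
                dist[id(nbr)] = dist[id(node)] + length
                stack.append(nbr)
    return dist


# ---------------------------------------------------------------------------
# Rooting


def root_with_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Root an (un)rooted tree at the midpoint of the outgroup's pendant edge.

    Leaf-to-leaf path lengths are unchanged.  The outgroup must name a leaf.
    """
    work = tree.copy()
    target = None
    for node in work.root.walk():
        for c in node.children:
            if c.is_leaf and c.name == outgroup:
                target = (node, c)
    if target is None:
        names = [n.name for n in work.root.walk() if not n.is_leaf and n.name]
        if outgroup in names or outgroup not in work.leaf_names():
            raise KeyError(f"outgroup {outgroup!r} is not a leaf of the tree")
        # outgroup is a leaf that is also the stored root (degenerate 1-node tree)
        raise KeyError(f"cannot root at {outgroup!r}")

    parent, leaf = target
    half = None if leaf.length is None else leaf.length / 2.0

    # Re-orient the tree so `parent` becomes a child chain hanging off the
    # new root.  Build the parent map first.
    parent_of: dict[int, Clade] = {}
    for node in work.root.walk():
        for c in node.children:
            parent_of[id(c)] = node

    def reoriented(node: Clade, coming_from: Clade) -> Clade:
        """`node` viewed as a child of `coming_from` (its old child)."""
        new = Clade(name=node.name)
        # edge between node and coming_from was stored on coming_from
        new.length = coming_from.length
        new.support = coming_from.support
        new.children = [c for c in node.children if c is not coming_from]
        up = parent_of.get(id(node))
        if up is not None:
            new.children.append(reoriented(up, node))
        if len(new.children) == 1 and not new.name:
            # suppress the degree-2 node left behind at the old root
            only = new.children[0]
            merged = Clade(
                name=only.name,
                length=_add(new.length, only.length),
                support=only.support if only.support is not None else new.support,
                children=only.children,
            )
            return merged
        return new

    rest = Clade(name=parent.name, length=half, support=leaf.support)
    rest.children = [c for c in parent.children if c is not leaf]
    up = parent_of.get(id(parent))
    if up is not None:
        rest.children.append(reoriented(up, parent))
    if len(rest.children) == 1 and not rest.name:
        only = rest.children[0]
        rest = Clade(
            name=only.name,
            length=_add(half, only.length),
            support=only.support,
            children=only.children,
        )
    new_root = Clade(children=[Clade(name=outgroup, length=half), rest])
    return PhyloTree(new_root, rooted=True)


def _add(a: float | None, b: float | None) -> float | None:
    if a is None and b is None:
        return None
    return (a or 0.0) + (b or 0.0)
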