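"""Dual bootstrap, majority-rule consensus, and differentiation ranking.

Branch stability is estimated with a dual resampling scheme: every
replicate (i) draws a gene subset of random size n ~ DiscreteUniform{1..N}
with replacement from the N selected differentially expressed genes, and
(ii) resamples, within every group, its n_i samples with replacement
(capturing classification uncertainty of the tumor samples).  Group
means, the distance matrix and the tree are then recomputed from scratch.

Replicate trees are summarized with an extended majority-rule consensus:
all bipartitions occurring in more than half the replicates are kept, and
remaining bipartitions are added greedily in descending frequency when
compatible.  Support values are the exact percentage of replicate trees
containing the bipartition.

The rooted consensus yields the differentiation ranking: walking the path
from the root (stem-cell outgroup) to the differentiated-reference leaf,
each subtype is assigned the branching point where it attaches to this
path; subtypes attaching at the same point share a tier.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .build import TREE_METHODS, neighbor_joining, search_topology, upgma
from .data import ExpressionMatrix, GroupAnnotation, group_column_order
from .distance import DistanceMatrix, distance_matrix
from .tree import Clade, PhyloTree

__all__ = [
    "BootstrapSpec",
    "ConsensusResult",
    "DegenerateReplicatesError",
    "Ranking",
    "draw_replicate",
    "majority_consensus",
    "rank_from_tree",
    "resolve_tree_method",
    "run_bootstrap",
]


class DegenerateReplicatesError(RuntimeError):
    """Raised when too many bootstrap replicates yield undefined distances."""


@dataclass
class BootstrapSpec:
    """Configuration of the dual bootstrap.

    ``replicates`` defaults to 10,000 (the full-scale setting); tests and
    examples use far fewer.  ``tree_method`` is one of nj/upgma/wls/me or
    any callable mapping a :class:`DistanceMatrix` to a :class:`PhyloTree`.
    """

    replicates: int = 10_000
    seed: int = 0
    resample_samples: bool = True
    tree_method: str = "wls"
    metric: str = "pearson"
    max_degenerate_fraction: float = 0.10
    exhaustive_max_leaves: int = 8


def resolve_tree_method(method, exhaustive_max_leaves: int = 8):
    """Return a callable DistanceMatrix -> PhyloTree for a method name."""
    if callable(method):
        return method
    if method == "nj":
        return neighbor_joining
    if method == "upgma":
        return upgma
    if method in ("wls", "me"):
        return lambda dm: search_topology(
            dm, criterion=method, exhaustive_max_leaves=exhaustive_max_leaves
        )[0]
    raise ValueError(f"unknown tree method {method!r}; valid: {TREE_METHODS}")


def draw_replicate(
    rng: np.random.Generator,
    genes: list[str],
    group_samples: dict[str, list[str]],
    resample_samples: bool = True,
) -> tuple[list[str], dict[str, list[str]]]:
    """One bootstrap draw: a gene multiset of uniform random size and a
    per-group sample resample of the original sizes."""
    N = len(genes)
    if N < 1:
        raise ValueError("need at least one selected gene")
    n = int(rng.integers(1, N + 1))
    gene_idx = rng.integers(0, N, size=n)
    gene_multiset = [genes[i] for i in gene_idx]
    if resample_samples:
        resampled = {
            g: [s[i] for i in rng.integers(0, len(s), size=len(s))]
            for g, s in group_samples.items()
        }
    else:
        resampled = {g: list(s) for g, s in group_samples.items()}
    return gene_multiset, resampled


def _replicate_distance(
    values: np.ndarray,
    gene_rows: np.ndarray,
    group_cols: list[np.ndarray],
    labels: list[str],
    metric: str,
) -> DistanceMatrix:
    sub = values[gene_rows]
    means = np.column_stack([sub[:, cols].mean(axis=1) for cols in group_cols])
    from .data import GroupMeanMatrix
    import pandas as pd

    gm = GroupMeanMatrix(
        pd.DataFrame(means, columns=labels, index=range(means.shape[0]))
    )
    return distance_matrix(gm, metric)


def run_bootstrap(
    x: ExpressionMatrix,
    a: GroupAnnotation,
    genes: list[str],
    spec: BootstrapSpec,
) -> tuple[list[PhyloTree], int]:
    """Run the dual bootstrap; returns (replicate trees, redraw count).

    Replicates whose distance matrix is undefined (constant profile under
    the Pearson metric, possible when a single gene is drawn) are redrawn;
    more than ``max_degenerate_fraction * replicates`` redraws abort.
    Deterministic given ``spec.seed``: replicate r uses the RNG stream
    seeded with (seed, r, attempt).
    """
    if spec.replicates < 0:
        raise ValueError("replicates must be >= 0")
    a.validate_against(x)
    if not genes:
        raise ValueError("empty gene selection; nothing to bootstrap")
    labels = group_column_order(a)
    values = x.values
    row_of = {g: i for i, g in enumerate(x.gene_ids)}
    col_of = {s: i for i, s in enumerate(x.sample_ids)}
    gene_rows_all = np.array([row_of[g] for g in genes])
    group_sample_cols = {
        g: np.array([col_of[s] for s in a.samples_of(g)]) for g in labels
    }
    builder = resolve_tree_method(spec.tree_method, spec.exhaustive_max_leaves)

    trees: list[PhyloTree] = []
    redraws = 0
    # the fractional threshold is meaningful at scale; a small floor keeps
    # low-R runs from aborting on the occasional single-gene draw
    max_redraws = max(10, int(spec.max_degenerate_fraction * spec.replicates))
    N = len(genes)
    for r in range(spec.replicates):
        attempt = 0
        while True:
            rng = np.random.default_rng([spec.seed, r, attempt])
            n = int(rng.integers(1, N + 1))
            gene_rows = gene_rows_all[rng.integers(0, N, size=n)]
            if spec.resample_samples:
                group_cols = [
                    cols[rng.integers(0, len(cols), size=len(cols))]
                    for cols in (group_sample_cols[g] for g in labels)
                ]
            else:
                group_cols = [group_sample_cols[g] for g in labels]
            try:
                dm = _replicate_distance(values, gene_rows, group_cols, labels, spec.metric)
                # a tree is part of the same degeneracy check: e.g. a tiny
                # gene draw can leave every pairwise distance exactly zero,
                # which no weighting scheme can fit
                tree = builder(dm)
            except ValueError:
                redraws += 1
                attempt += 1
                if redraws > max_redraws:
                    raise DegenerateReplicatesError(
                        f"{redraws} degenerate replicates exceed "
                        f"{spec.max_degenerate_fraction:.0%} of {spec.replicates}"
                    )
                continue
            trees.append(tree)
            break
    return trees, redraws


# ---------------------------------------------------------------------------
# Consensus


@dataclass
class ConsensusResult:
    """Extended majority-rule consensus tree with per-branch support (%)."""

    tree: PhyloTree
    supports: dict[frozenset, float]
    n_trees: int


def _split_sort_key(split: frozenset) -> str:
    return ",".join(sorted(split))


def _compatible(a: frozenset, b: frozenset) -> bool:
    # both sides oriented away from a common reference leaf
    return a.isdisjoint(b) or a <= b or b <= a


def majority_consensus(trees: list[PhyloTree]) -> ConsensusResult:
    """Extended majority-rule consensus of replicate trees.

    Splits in more than half the trees are always kept; the remainder are
    added greedily in descending frequency (ties by canonical split order)
    when compatible with everything already accepted.  Supports are exact
    empirical percentages rounded to 0.1.
    """
    if not trees:
        raise ValueError("consensus of zero trees is undefined")
    leaf_sets = {frozenset(t.leaf_names()) for t in trees}
    if len(leaf_sets) != 1:
        raise ValueError("all trees must share the same leaf set")
    all_leaves = leaf_sets.pop()
    R = len(trees)

    tally: Counter = Counter()
    for t in trees:
        for split in t.bipartitions():
            tally[split] += 1

    accepted: list[tuple[frozenset, int]] = []
    strict = [(s, c) for s, c in tally.items() if c * 2 > R]
    strict.sort(key=lambda sc: (-sc[1], _split_sort_key(sc[0])))
    accepted.extend(strict)
    rest = [(s, c) for s, c in tally.items() if c * 2 <= R]
    rest.sort(key=lambda sc: (-sc[1], _split_sort_key(sc[0])))
    for s, c in rest:
        if all(_compatible(s, t) for t, _ in accepted):
            accepted.append((s, c))

    supports = {s: round(100.0 * c / R, 1) for s, c in accepted}
    tree = _tree_from_splits(all_leaves, [s for s, _ in accepted], supports)
    return ConsensusResult(tree, supports, R)


def _tree_from_splits(
    all_leaves: frozenset, splits: list[frozenset], supports: dict[frozenset, float]
) -> PhyloTree:
    """Build the unrooted tree whose internal edges realize the given
    (pairwise compatible, reference-oriented) splits."""
    ref = min(all_leaves)
    ordered = sorted(splits, key=lambda s: (len(s), _split_sort_key(s)))
    clades = {s: Clade(support=supports.get(s)) for s in ordered}
    top = Clade()
    # parent of each cluster = the smallest strictly-containing cluster
    for i, s in enumerate(ordered):
        parent = None
        for t in ordered[i + 1 :]:
            if s < t:
                parent = clades[t]
                break
        (parent.children if parent else top.children).append(clades[s])
    for leaf in sorted(all_leaves - {ref}):
        parent = None
        for s in ordered:
            if leaf in s:
                parent = clades[s]
                break
        (parent.children if parent else top.children).append(Clade(name=leaf))
    top.children.append(Clade(name=ref))
    return PhyloTree(top, rooted=False)


# ---------------------------------------------------------------------------
# Ranking


@dataclass
class Ranking:
    """Ordered tiers of subtype labels, closest-to-root first.

    Subtypes sharing a tier attach to the differentiation path at the same
    branching point and cannot be distinguished in maturity.
    """

    tiers: list[list[str]] = field(default_factory=list)

    def flat(self) -> list[str]:
        return [label for tier in self.tiers for label in tier]

    def __str__(self) -> str:
        return " < ".join(
            tier[0] if len(tier) == 1 else "{" + ",".join(tier) + "}"
            for tier in self.tiers
        )


def rank_from_tree(
    tree: PhyloTree,
    root_label: str,
    ref_label: str,
    subtypes: list[str] | None = None,
) -> Ranking:
    """Differentiation ranking of subtype leaves along the root->reference path.

    Each subtype leaf is assigned the node where its path to the root first
    meets the root->reference path ("differentiation path"); tiers follow
    the order of those attachment nodes from the root.
    """
    names = tree.leaf_names()
    for label in (root_label, ref_label):
        if label not in names:
            raise KeyError(f"leaf {label!r} not present in tree")
    if subtypes is None:
        subtypes = [l for l in names if l not in (root_label, ref_label)]
    else:
        missing = [s for s in subtypes if s not in names]
        if missing:
            raise KeyError(f"subtype leaf/leaves missing from tree: {missing}")

    parent_of: dict[int, Clade] = {}
    node_by_id: dict[int, Clade] = {id(tree.root): tree.root}
    for node in tree.root.walk():
        node_by_id[id(node)] = node
        for c in node.children:
            parent_of[id(c)] = node

    def path_to_top(leaf_name: str) -> list[Clade]:
        node = next(n for n in tree.root.walk() if n.is_leaf and n.name == leaf_name)
        path = [node]
        while id(node) in parent_of:
            node = parent_of[id(node)]
            path.append(node)
        return path

    root_path = path_to_top(root_label)
    ref_path = path_to_top(ref_label)
    root_ids = {id(n): k for k, n in enumerate(root_path)}
    # meet point of the two paths = first shared node walking up from ref
    meet_idx = next(root_ids[id(n)] for n in ref_path if id(n) in root_ids)
    # differentiation path, ordered from the root leaf to the reference leaf
    diff_path = root_path[1 : meet_idx + 1] + [
        n for n in reversed([m for m in ref_path if id(m) not in root_ids])
    ][:-1]
    position = {id(n): k for k, n in enumerate(diff_path)}

    attach: dict[str, int] = {}
    for label in subtypes:
        for node in path_to_top(label):
            if id(node) in position:
                attach[label] = position[id(node)]
                break
    tiers: dict[int, list[str]] = {}
    for label, k in attach.items():
        tiers.setdefault(k, []).append(label)
    return Ranking([sorted(tiers[k]) for k in sorted(tiers)])
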