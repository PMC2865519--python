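"""Comparison methods: greedy linear ordering and minimum spanning trees.

These are the simpler organizations the phylogenetic approach is compared
against: a naive ordering of subtypes by their distance from the stem-cell
anchor, and Prim's minimum spanning tree on the distance graph.  Both can
be bootstrapped with the same replicate scheme as the trees; since there
is no established consensus algorithm for MSTs, per-edge occurrence
frequencies are reported instead of a consensus structure.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import group_column_order
from .distance import DistanceMatrix

__all__ = [
    "LinearOrder",
    "SpanningTree",
    "bootstrap_greedy_positions",
    "bootstrap_mst_edges",
    "greedy_order",
    "minimum_spanning_tree",
]


@dataclass
class LinearOrder:
    """Labels ordered by non-decreasing distance from the anchor."""

    anchor: str
    entries: list[tuple[str, float]]  # (label, distance to anchor)

    @property
    def labels(self) -> list[str]:
        return [l for l, _ in self.entries]


@dataclass
class SpanningTree:
    edges: list[tuple[str, str, float]]
    total_weight: float


def greedy_order(dm: DistanceMatrix, anchor: str) -> LinearOrder:
    """Sort all non-anchor labels by their distance to the anchor.

    Ties are broken lexicographically; the anchor is excluded from its own
    ordering.
    """
    if anchor not in dm.labels:
        raise KeyError(f"anchor {anchor!r} not in distance matrix")
    i = dm.labels.index(anchor)
    entries = sorted(
        ((l, float(dm.values[i, j])) for j, l in enumerate(dm.labels) if j != i),
        key=lambda ld: (ld[1], ld[0]),
    )
    return LinearOrder(anchor, entries)


def minimum_spanning_tree(dm: DistanceMatrix) -> SpanningTree:
    """Prim's algorithm from the first label; ties by smallest label index."""
    n = len(dm)
    if n < 2:
        raise ValueError("MST needs at least 2 labels")
    D = dm.values
    in_tree = [0]
    out = list(range(1, n))
    edges: list[tuple[str, str, float]] = []
    total = 0.0
    while out:
        best = None  # (weight, tree_idx, out_idx)
        for u in in_tree:
            for v in out:
                cand = (D[u, v], u, v)
                if best is None or cand < best:
                    best = cand
        w, u, v = best
        edges.append((dm.labels[u], dm.labels[v], float(w)))
        total += float(w)
        in_tree.append(v)
        out.remove(v)
    return SpanningTree(edges, total)


def bootstrap_greedy_positions(
    x, a, genes, spec, anchor: str
) -> pd.DataFrame:
    """Fraction of bootstrap replicates in which each label occupies each
    position of the greedy ordering (labels x positions)."""
    orders = _bootstrap_distances(x, a, genes, spec, lambda dm: greedy_order(dm, anchor))
    labels = [l for l in group_column_order(a) if l != anchor]
    counts = {l: Counter() for l in labels}
    for order in orders:
        for pos, label in enumerate(order.labels):
            counts[label][pos] += 1
    R = len(orders)
    table = pd.DataFrame(
        [[counts[l][p] / R for p in range(len(labels))] for l in labels],
        index=labels,
        columns=[f"pos_{p+1}" for p in range(len(labels))],
    )
    return table


def bootstrap_mst_edges(x, a, genes, spec) -> pd.DataFrame:
    """Per-edge occurrence frequency of the MST across bootstrap replicates."""
    msts = _bootstrap_distances(x, a, genes, spec, minimum_spanning_tree)
    tally: Counter = Counter()
    for t in msts:
        for u, v, _ in t.edges:
            tally[tuple(sorted((u, v)))] += 1
    R = len(msts)
    rows = [(u, v, c / R) for (u, v), c in sorted(tally.items(), key=lambda kv: -kv[1])]
    return pd.DataFrame(rows, columns=["label_a", "label_b", "frequency"])


def _bootstrap_distances(x, a, genes, spec, summarize):
    """Run the shared dual-bootstrap replicate scheme, summarizing each
    replicate's distance matrix with ``summarize``."""
    from . import bootstrap as _bs  # deferred: bootstrap imports build at load

    labels = group_column_order(a)
    values = x.values
    row_of = {g: i for i, g in enumerate(x.gene_ids)}
    col_of = {s: i for i, s in enumerate(x.sample_ids)}
    gene_rows_all = np.array([row_of[g] for g in genes])
    group_sample_cols = {
        g: np.array([col_of[s] for s in a.samples_of(g)]) for g in labels
    }
    N = len(genes)
    out = []
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
                dm = _bs._replicate_distance(
                    values, gene_rows, group_cols, labels, spec.metric
                )
            except ValueError:
                attempt += 1
                continue
            out.append(summarize(dm))
            break
    return out
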