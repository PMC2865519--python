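"""Distance-based tree reconstruction: NJ, UPGMA, WLS and ME searches.

The weighted least squares (WLS, Fitch-Margoliash) objective drives both
explicit searches:

    E = sum_{i<j} (delta_ij - d^T_ij)^2 / delta_ij^2

where delta are the observed distances and d^T the path lengths on the
candidate tree.  The 1/delta^2 weights down-weight deviations between
distantly related groups, which matters here because the in-vitro
outgroups (stem cells) are far from every tumor subtype.  Branch lengths
are fit by non-negative least squares on the path-incidence system; the
minimum evolution (ME) criterion scores each topology by the sum of its
WLS branch-length estimates instead of by E.  Following the classical ME
convention, that sum is taken over the unconstrained (possibly negative)
estimates — clamping before summation would let wrong topologies shed
length artificially — while the returned tree always carries the
non-negative constrained fit.

For <= 8 leaves the searches enumerate all (2n-5)!! unrooted topologies
exhaustively (a branch-and-bound over the unconstrained solutions keeps
this fast); for more leaves a deterministic stepwise-addition +
nearest-neighbor-interchange hill climb is used.  Ties are broken by
canonical Newick order so results are reproducible.

The tree-fit report combines E with the average percent standard
deviation (apsd), 100 * sqrt(mean of squared relative deviations), the
conventional fit-quality score for correlation distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import nnls

from .distance import DistanceMatrix
from .tree import Clade, PhyloTree, path_distance_matrix

__all__ = [
    "TreeFit",
    "average_percent_sd",
    "fit_branch_lengths",
    "neighbor_joining",
    "search_topology",
    "upgma",
]

TREE_METHODS = ("nj", "upgma", "wls", "me")

_NEG_TOL = 1e-10


@dataclass
class TreeFit:
    """WLS objective E and average percent standard deviation of a fitted tree."""

    objective: float
    apsd: float


# ---------------------------------------------------------------------------
# Neighbor-Joining


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei Neighbor-Joining; negative branch lengths clamped to zero.

    Ties in the Q criterion are broken by the first (i, j) pair in index
    order, so the result is deterministic.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    D = dm.values.astype(float).copy()
    nodes: list[Clade] = [Clade(name=l) for l in dm.labels]

    while len(nodes) > 3:
        r = len(nodes)
        sums = D.sum(axis=1)
        Q = (r - 2) * D - sums[:, None] - sums[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = _first_argmin(Q)
        li = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = D[i, j] - li
        ci, cj = nodes[i], nodes[j]
        ci.length = max(li, 0.0)
        cj.length = max(lj, 0.0)
        new = Clade(children=[ci, cj])
        dk = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D_new = np.empty((r - 1, r - 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = D_new[:-1, -1] = dk[keep]
        D_new[-1, -1] = 0.0
        D = D_new
        nodes = [nodes[k] for k in keep] + [new]

    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = max(0.5 * (dab + dac - dbc), 0.0)
    b.length = max(0.5 * (dab + dbc - dac), 0.0)
    c.length = max(0.5 * (dac + dbc - dab), 0.0)
    return PhyloTree(Clade(children=[a, b, c]), rooted=False)


def _first_argmin(M: np.ndarray) -> tuple[int, int]:
    flat = np.argmin(M)
    best = M.flat[flat]
    hits = np.argwhere(M <= best + 0.0)
    hits = hits[hits[:, 0] < hits[:, 1]]
    if len(hits) == 0:  # matrix symmetric; fall back to the flat argmin
        return divmod(int(flat), M.shape[1])
    i, j = min(map(tuple, hits))
    return int(i), int(j)


# ---------------------------------------------------------------------------
# UPGMA


def upgma(dm: DistanceMatrix) -> PhyloTree:
    """Average-linkage agglomeration; returns a rooted ultrametric tree.

    Node heights are half the merge distance, so all leaf-to-root path
    lengths are equal when the input is ultrametric.  Cluster updates use
    size-weighted averages; tie-break is the first pair in index order.
    """
    n = len(dm)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 labels")
    D = dm.values.astype(float).copy()
    nodes: list[Clade] = [Clade(name=l) for l in dm.labels]
    heights = [0.0] * n
    sizes = [1] * n

    while len(nodes) > 1:
        r = len(nodes)
        M = D.copy()
        np.fill_diagonal(M, np.inf)
        i, j = _first_argmin(M)
        h = D[i, j] / 2.0
        ci, cj = nodes[i], nodes[j]
        ci.length = max(h - heights[i], 0.0)
        cj.length = max(h - heights[j], 0.0)
        new = Clade(children=[ci, cj])
        ni, nj = sizes[i], sizes[j]
        dk = (ni * D[i] + nj * D[j]) / (ni + nj)
        keep = [k for k in range(r) if k not in (i, j)]
        D_new = np.empty((r - 1, r - 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = D_new[:-1, -1] = dk[keep]
        D_new[-1, -1] = 0.0
        D = D_new
        nodes = [nodes[k] for k in keep] + [new]
        heights = [heights[k] for k in keep] + [h]
        sizes = [sizes[k] for k in keep] + [ni + nj]

    return PhyloTree(nodes[0], rooted=True)


# ---------------------------------------------------------------------------
# Topology enumeration and incidence matrices

_TOPOLOGY_CACHE: dict[int, tuple[list[list[tuple[int, int]]], np.ndarray]] = {}


def _enumerate_topologies(n: int) -> list[list[tuple[int, int]]]:
    """All (2n-5)!! unrooted binary topologies on leaves 0..n-1.

    Internal nodes are numbered from n upward; leaf k (k >= 3) introduces
    internal node n + k - 2 when inserted.
    """
    base = [[(0, n), (1, n), (2, n)]]
    for leaf in range(3, n):
        new_internal = n + leaf - 2
        grown = []
        for edges in base:
            for e_idx, (u, v) in enumerate(edges):
                new_edges = edges[:e_idx] + edges[e_idx + 1 :]
                new_edges = new_edges + [
                    (u, new_internal),
                    (v, new_internal),
                    (leaf, new_internal),
                ]
                grown.append(new_edges)
        base = grown
    return base


def _incidence(edges: list[tuple[int, int]], n: int) -> np.ndarray:
    """Pairs x edges 0/1 matrix: row (i,j) marks edges on the i-j leaf path."""
    adj: dict[int, list[tuple[int, int]]] = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))

    paths_from: dict[int, dict[int, frozenset]] = {}
    for leaf in range(n):
        seen = {leaf: frozenset()}
        stack = [leaf]
        while stack:
            node = stack.pop()
            for nbr, eidx in adj[node]:
                if nbr not in seen:
                    seen[nbr] = seen[node] | {eidx}
                    stack.append(nbr)
        paths_from[leaf] = seen

    pairs = list(combinations(range(n), 2))
    A = np.zeros((len(pairs), len(edges)))
    for row, (i, j) in enumerate(pairs):
        for eidx in paths_from[i][j]:
            A[row, eidx] = 1.0
    return A


def _topology_cache(n: int):
    if n not in _TOPOLOGY_CACHE:
        topologies = _enumerate_topologies(n)
        A = np.stack([_incidence(t, n) for t in topologies])
        _TOPOLOGY_CACHE[n] = (topologies, A)
    return _TOPOLOGY_CACHE[n]


def _tree_from_edges(
    edges: list[tuple[int, int]],
    lengths: np.ndarray,
    labels: list[str],
) -> PhyloTree:
    n = len(labels)
    length_of = {frozenset(e): float(l) for e, l in zip(edges, lengths)}
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    # anchor at the internal neighbor of leaf 0 (internal ids are >= n)
    anchor = adj[0][0] if n > 1 else 0

    def build(node: int, parent: int | None) -> Clade:
        clade = Clade(name=labels[node] if node < n else None)
        if parent is not None:
            clade.length = length_of[frozenset((node, parent))]
        clade.children = [build(c, node) for c in adj[node] if c != parent]
        return clade

    return PhyloTree(build(anchor, None), rooted=False)


# ---------------------------------------------------------------------------
# WLS branch-length fitting


def _wls_weights(delta: np.ndarray, zero_policy: str) -> np.ndarray:
    if zero_policy not in ("strict", "lenient"):
        raise ValueError("zero_policy must be 'strict' or 'lenient'")
    zero = delta <= 0.0
    if zero.any():
        if zero_policy == "strict":
            raise ValueError(
                "zero observed distance between distinct groups; "
                "1/delta^2 weight undefined (strict mode)"
            )
        positive = delta[~zero]
        if positive.size == 0:
            raise ValueError("all observed distances are zero")
        delta = np.where(zero, positive.min(), delta)
    return 1.0 / delta**2


def _fit_condensed(
    A: np.ndarray, delta: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, float]:
    """Non-negative WLS solve of A b ~ delta with weights w; returns (b, E)."""
    sw = np.sqrt(w)
    Aw = A * sw[:, None]
    dw = delta * sw
    M = Aw.T @ Aw
    try:
        b = np.linalg.solve(M, Aw.T @ dw)
    except np.linalg.LinAlgError:
        b = np.linalg.lstsq(Aw, dw, rcond=None)[0]
    if b.min() < -_NEG_TOL:
        b, _ = nnls(Aw, dw)
    b = np.clip(b, 0.0, None)
    resid = A @ b - delta
    return b, float((w * resid**2).sum())


def fit_branch_lengths(
    tree: PhyloTree,
    dm: DistanceMatrix,
    zero_policy: str = "lenient",
) -> tuple[PhyloTree, TreeFit]:
    """Fit non-negative WLS branch lengths of ``tree``'s topology to ``dm``.

    Works for multifurcating trees (e.g. consensus topologies).  Returns a
    new tree with lengths assigned and the :class:`TreeFit` report.
    """
    if set(tree.leaf_names()) != set(dm.labels):
        raise ValueError("tree leaf set does not match distance-matrix labels")
    work = tree.copy()
    # edge k <-> the k-th non-root clade in preorder
    clades = [c for c in work.root.walk() if c is not work.root]
    index_of = {id(c): k for k, c in enumerate(clades)}
    labels = sorted(dm.labels)
    pos = {l: i for i, l in enumerate(labels)}
    pairs = list(combinations(range(len(labels)), 2))
    pair_row = {p: r for r, p in enumerate(pairs)}
    A = np.zeros((len(pairs), len(clades)))

    def leafset(node: Clade) -> list[int]:
        if node.is_leaf:
            return [pos[node.name]]
        out: list[int] = []
        for c in node.children:
            out.extend(leafset(c))
        return out

    below = {id(c): set(leafset(c)) for c in clades}
    all_idx = set(range(len(labels)))
    for c in clades:
        inside = below[id(c)]
        for i in inside:
            for j in all_idx - inside:
                A[pair_row[(min(i, j), max(i, j))], index_of[id(c)]] = 1.0

    delta = dm.reorder(labels).condensed()
    w = _wls_weights(delta, zero_policy)
    b, E = _fit_condensed(A, delta, w)
    for c in clades:
        c.length = float(b[index_of[id(c)]])
    m = len(pairs)
    return work, TreeFit(E, 100.0 * float(np.sqrt(E / m)))


def average_percent_sd(
    dm: DistanceMatrix, tree: PhyloTree, zero_policy: str = "strict"
) -> float:
    """apsd = 100 * sqrt(mean over pairs of ((d^T - delta) / delta)^2)."""
    labels = sorted(dm.labels)
    delta = dm.reorder(labels).condensed()
    dT = path_distance_matrix(tree).reorder(labels).condensed()
    if (delta <= 0).any():
        if zero_policy == "strict":
            raise ValueError("zero observed distance; apsd undefined (strict mode)")
        delta = np.where(delta <= 0, delta[delta > 0].min(), delta)
    rel = (dT - delta) / delta
    return 100.0 * float(np.sqrt((rel**2).mean()))


# ---------------------------------------------------------------------------
# Topology search


def search_topology(
    dm: DistanceMatrix,
    criterion: str = "wls",
    exhaustive_max_leaves: int = 8,
    zero_policy: str = "lenient",
) -> tuple[PhyloTree, TreeFit]:
    """Best unrooted topology under the WLS or ME criterion.

    ``wls`` minimizes the weighted sum-of-squares E; ``me`` minimizes the
    total WLS-fitted branch length.  Exhaustive for up to
    ``exhaustive_max_leaves`` leaves; stepwise addition + NNI beyond.
    """
    if criterion not in ("wls", "me"):
        raise ValueError("criterion must be 'wls' or 'me'")
    labels = list(dm.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("topology search needs at least 3 labels")
    delta = dm.condensed()
    w = _wls_weights(delta, zero_policy)
    if n <= exhaustive_max_leaves:
        edges, b = _search_exhaustive(n, delta, w, criterion)
    else:
        edges, b = _search_heuristic(n, delta, w, criterion)
    tree = _tree_from_edges(edges, b, labels)
    A = _incidence(edges, n)
    resid = A @ b - delta
    E = float((w * resid**2).sum())
    return tree, TreeFit(E, 100.0 * float(np.sqrt(E / len(delta))))


def _constrained(A, delta, w, b_unc):
    if b_unc.min() >= -_NEG_TOL:
        b = np.clip(b_unc, 0.0, None)
        resid = A @ b - delta
        return b, float((w * resid**2).sum())
    sw = np.sqrt(w)
    b, rnorm = nnls(A * sw[:, None], delta * sw)
    return b, float(rnorm**2)


def _search_exhaustive(n, delta, w, criterion):
    topologies, A_stack = _topology_cache(n)
    Aw = A_stack * w[None, :, None]
    M = np.einsum("tpe,tpf->tef", Aw, A_stack)
    rhs = np.einsum("tpe,p->te", Aw, delta)
    # relative ridge guards against near-singular systems when the 1/delta^2
    # weights span many orders of magnitude; negligible for healthy systems
    n_edges = M.shape[-1]
    diag_scale = np.einsum("tee->t", M) / n_edges
    M = M + (1e-10 * diag_scale)[:, None, None] * np.eye(n_edges)[None]
    try:
        b_unc = np.linalg.solve(M, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        b_unc = np.stack(
            [np.linalg.lstsq(M[t], rhs[t], rcond=None)[0] for t in range(M.shape[0])]
        )
    fitted = np.einsum("tpe,te->tp", A_stack, b_unc)
    E_unc = (w[None, :] * (fitted - delta) ** 2).sum(axis=1)

    best_score = np.inf
    best: list[tuple] = []  # (canonical key tie-break applied at the end)
    if criterion == "wls":
        order = np.argsort(E_unc, kind="stable")
        for t in order:
            if best:
                tol = 1e-12 * max(1.0, best_score)
                if E_unc[t] > best_score + tol + 1e-15:
                    break  # unconstrained E lower-bounds constrained E
            b, E = _constrained(A_stack[t], delta, w, b_unc[t])
            tol = 1e-12 * max(1.0, best_score if best else E)
            if not best or E < best_score - tol:
                best_score, best = E, [(t, b)]
            elif E <= best_score + tol:
                best.append((t, b))
    else:  # me
        # classical minimum evolution scores the sum of the (possibly
        # negative) least-squares branch-length estimates; clamping before
        # summation would let wrong topologies shed length artificially
        scores = b_unc.sum(axis=1)
        best_score = scores.min()
        best = [
            (t, _constrained(A_stack[t], delta, w, b_unc[t])[0])
            for t in range(len(topologies))
            if scores[t] <= best_score + 1e-12 * max(1.0, abs(best_score))
        ]

    if len(best) == 1:
        t, b = best[0]
        return topologies[t], b
    # deterministic tie-break: smallest canonical Newick string
    keyed = []
    for t, b in best:
        tree = _tree_from_edges(topologies[t], b, [str(i) for i in range(n)])
        keyed.append((tree.canonical_newick(), t, b))
    keyed.sort(key=lambda kv: kv[0])
    _, t, b = keyed[0]
    return topologies[t], b


def _score_edges(edges, n, delta, w, criterion):
    A = _incidence(edges, n)
    sw = np.sqrt(w)
    Aw = A * sw[:, None]
    dw = delta * sw
    if criterion == "me":
        # score by the unconstrained least-squares length sum (see above)
        M = Aw.T @ Aw + 1e-12 * np.eye(A.shape[1])
        b_unc = np.linalg.solve(M, Aw.T @ dw)
        b, _ = _constrained(A, delta, w, b_unc)
        resid = A @ b - delta
        return float(b_unc.sum()), b, float((w * resid**2).sum())
    b, rnorm = nnls(Aw, dw)
    E = float(rnorm**2)
    return E, b, E


def _search_heuristic(n, delta, w, criterion):
    """Stepwise addition in label order, then NNI hill climbing."""
    pairs = list(combinations(range(n), 2))
    pair_row = {p: r for r, p in enumerate(pairs)}

    def sub_delta_w(leaves):
        rows = [pair_row[p] for p in combinations(sorted(leaves), 2)]
        return delta[rows], w[rows]

    edges = [(0, n), (1, n), (2, n)]
    present = [0, 1, 2]
    for leaf in range(3, n):
        new_internal = n + leaf - 2
        cand_leaves = sorted(present + [leaf])
        d_sub, w_sub = sub_delta_w(cand_leaves)
        # renumber leaves 0..m-1 for incidence computation
        remap = {l: i for i, l in enumerate(cand_leaves)}
        best = None
        for e_idx, (u, v) in enumerate(edges):
            trial = edges[:e_idx] + edges[e_idx + 1 :]
            trial += [(u, new_internal), (v, new_internal), (leaf, new_internal)]
            mapped = _remap_edges(trial, remap, len(cand_leaves))
            score, b, E = _score_edges(mapped, len(cand_leaves), d_sub, w_sub, criterion)
            if best is None or score < best[0] - 1e-15:
                best = (score, trial)
        edges = best[1]
        present = cand_leaves

    remap = {l: l for l in range(n)}
    score, b, _ = _score_edges(_remap_edges(edges, remap, n), n, delta, w, criterion)
    improved = True
    rounds = 0
    while improved and rounds < 100:
        improved = False
        rounds += 1
        for alt in _nni_neighbors(edges, n):
            mapped = _remap_edges(alt, remap, n)
            alt_score, alt_b, _ = _score_edges(mapped, n, delta, w, criterion)
            if alt_score < score - 1e-13 * max(1.0, score):
                edges, score, b = alt, alt_score, alt_b
                improved = True
                break
    return _remap_edges(edges, remap, n), b


def _remap_edges(edges, leaf_remap, n_leaves):
    """Renumber so leaves are 0..n-1 and internal nodes n..; order-preserving."""
    internal: dict[int, int] = {}
    out = []
    next_internal = n_leaves

    def node_id(x):
        nonlocal next_internal
        if x in leaf_remap:
            return leaf_remap[x]
        if x not in internal:
            internal[x] = next_internal
            next_internal += 1
        return internal[x]

    for u, v in edges:
        out.append((node_id(u), node_id(v)))
    return out


def _nni_neighbors(edges, n):
    """The two nearest-neighbor-interchange rearrangements of each internal edge."""
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    edge_set = {frozenset(e) for e in edges}
    for u, v in edges:
        if u < n or v < n:
            continue  # pendant edge
        u_nbrs = [x for x in adj[u] if x != v]
        v_nbrs = [x for x in adj[v] if x != u]
        a, b = u_nbrs[0], u_nbrs[1]
        c, d = v_nbrs[0], v_nbrs[1]
        # swap b <-> c and b <-> d
        for x, y in ((b, c), (b, d)):
            new = set(edge_set)
            new -= {frozenset((u, x)), frozenset((v, y))}
            new |= {frozenset((u, y)), frozenset((v, x))}
            yield [tuple(sorted(e)) for e in sorted(new, key=lambda s: sorted(s))]
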