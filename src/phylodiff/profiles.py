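"""Expression-profile clustering over the differentiation ranking.

Once the subtypes are ordered by their dissimilarity from stem cells, the
per-group mean profile of every selected gene is standardized (z-score
across the ordered columns, sample sd) and clustered with fuzzy c-means.
Clusters whose centroid changes monotonically along the order — expression
continuously increasing toward the differentiated reference, or
continuously decreasing — collect the genes hypothesized to be related to
gain of differentiation features or loss of stem-cell-associated
functions.  Those genes are finally ranked by the fold change between the
root outgroup (stem cells) and the differentiated reference.

Fuzzy c-means: membership u_ik proportional to (1/||x_i - v_k||^2)^(1/(m-1)),
centroid v_k = sum_i u_ik^m x_i / sum_i u_ik^m, iterated until the largest
centroid movement falls below ``tol``.  The fuzzifier m (> 1) controls the
softness of memberships; m -> 1 recovers hard k-means assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GroupMeanMatrix

__all__ = [
    "ClusterModel",
    "ProfileMatrix",
    "fold_change_ranking",
    "fold_from_log_ratio",
    "fuzzy_cmeans",
    "log_ratio_from_fold",
    "monotone_clusters",
    "standardize_profiles",
]


@dataclass
class ProfileMatrix:
    """Row-standardized (mean 0, sd 1) group-mean profiles over ordered columns."""

    frame: pd.DataFrame  # genes x ordered groups
    dropped_constant: list[str]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def order(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()


def standardize_profiles(means: GroupMeanMatrix, order: list[str]) -> ProfileMatrix:
    """Z-score each gene's mean profile across the ordered columns (sd with n-1).

    Constant rows, whose sd is zero, are dropped and reported.
    """
    missing = [g for g in order if g not in means.groups]
    if missing:
        raise KeyError(f"order label(s) not in mean matrix: {missing}")
    if len(order) < 2:
        raise ValueError("need at least 2 ordered columns to standardize")
    sub = means.frame[list(order)]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    constant = sd <= 0.0
    dropped = list(sub.index[constant])
    z = sub.loc[~constant].sub(mu[~constant], axis=0).div(sd[~constant], axis=0)
    return ProfileMatrix(z, dropped)


@dataclass
class ClusterModel:
    centroids: pd.DataFrame  # clusters x columns
    membership: pd.DataFrame  # genes x clusters
    m: float
    n_iter: int
    converged: bool
    objective_trace: list[float]


def fuzzy_cmeans(
    profiles: ProfileMatrix,
    c: int = 20,
    m: float = 1.25,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> ClusterModel:
    """Fuzzy c-means clustering of standardized profiles.

    Deterministic given ``seed`` (centroids initialized from c distinct
    random profiles).  Membership rows sum to one at every iteration.
    """
    X = profiles.values
    n, _ = X.shape
    if c < 1:
        raise ValueError("c must be >= 1")
    if c > n:
        raise ValueError(f"c={c} clusters but only {n} profiles")
    if m <= 1.0:
        raise ValueError("fuzzifier m must be > 1")
    rng = np.random.default_rng(seed)
    centroids = X[rng.choice(n, size=c, replace=False)].astype(float).copy()

    exponent = 1.0 / (m - 1.0)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)  # n x c
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-exponent)
            u = inv / inv.sum(axis=1, keepdims=True)
        rows_on_centroid = zero.any(axis=1)
        if rows_on_centroid.any():
            u[rows_on_centroid] = zero[rows_on_centroid] / zero[rows_on_centroid].sum(
                axis=1, keepdims=True
            )
        um = u**m
        trace.append(float((um * d2).sum()))
        new_centroids = (um.T @ X) / um.sum(axis=0)[:, None]
        shift = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if shift < tol:
            converged = True
            break

    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    zero = d2 <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-exponent)
        u = inv / inv.sum(axis=1, keepdims=True)
    rows_on_centroid = zero.any(axis=1)
    if rows_on_centroid.any():
        u[rows_on_centroid] = zero[rows_on_centroid] / zero[rows_on_centroid].sum(
            axis=1, keepdims=True
        )
    cluster_ids = [f"C{k+1}" for k in range(c)]
    return ClusterModel(
        centroids=pd.DataFrame(centroids, index=cluster_ids, columns=profiles.order),
        membership=pd.DataFrame(u, index=profiles.gene_ids, columns=cluster_ids),
        m=m,
        n_iter=it,
        converged=converged,
        objective_trace=trace,
    )


def centroid_direction(v: np.ndarray, tol: float = 1e-9) -> str | None:
    """'increasing'/'decreasing' for a monotone centroid with at least one
    strict step, else None."""
    steps = np.diff(np.asarray(v, dtype=float))
    if (steps >= -tol).all() and (steps > tol).any():
        return "increasing"
    if (steps <= tol).all() and (steps < -tol).any():
        return "decreasing"
    return None


def monotone_clusters(
    model: ClusterModel, membership_threshold: float = 0.5
) -> pd.DataFrame:
    """Genes whose maximal membership lies in a monotone cluster.

    Returns a table (gene_id, cluster, membership, direction); a cluster is
    monotone iff its centroid is non-decreasing or non-increasing across
    the ordered columns with at least one strict step.
    """
    directions = {
        cid: centroid_direction(model.centroids.loc[cid].to_numpy())
        for cid in model.centroids.index
    }
    best = model.membership.idxmax(axis=1)
    best_u = model.membership.max(axis=1)
    rows = []
    for gene, cid, u in zip(model.membership.index, best, best_u):
        direction = directions[cid]
        if direction is not None and u >= membership_threshold:
            rows.append((gene, cid, float(u), direction))
    return pd.DataFrame(rows, columns=["gene_id", "cluster", "membership", "direction"])


def fold_from_log_ratio(delta: float) -> float:
    """Signed linear fold for a log2 ratio: 2^d for d >= 0, else -2^(-d)."""
    return float(2.0**delta) if delta >= 0 else float(-(2.0**-delta))


def log_ratio_from_fold(fold: float) -> float:
    """Inverse of :func:`fold_from_log_ratio` (|fold| must be >= 1)."""
    if abs(fold) < 1.0:
        raise ValueError("signed fold convention requires |fold| >= 1")
    return float(np.log2(fold)) if fold > 0 else float(-np.log2(-fold))


def fold_change_ranking(
    monotone: pd.DataFrame,
    means: GroupMeanMatrix,
    root_label: str,
    ref_label: str,
) -> pd.DataFrame:
    """Rank monotone genes by |fold change| between outgroup and reference.

    The log2 ratio is mean(reference) - mean(root outgroup); the signed
    linear fold is 2^d for d >= 0 and -2^(-d) otherwise, so halving in
    expression displays as -2 rather than 0.5.
    """
    for label in (root_label, ref_label):
        if label not in means.groups:
            raise KeyError(f"group {label!r} not in mean matrix")
    sub = means.frame.loc[list(monotone["gene_id"])]
    delta = (sub[ref_label] - sub[root_label]).to_numpy()
    folds = np.array([fold_from_log_ratio(d) for d in delta])
    out = monotone.copy()
    out["log2_ratio"] = delta
    out["fold_change"] = folds
    out = out.sort_values(
        by="fold_change", key=lambda s: s.abs(), ascending=False, kind="stable"
    )
    return out.reset_index(drop=True)
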