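"""Observed distance matrices between group mean expression profiles.

Two metrics are supported, both computed on the selected (differentially
expressed) genes: the Pearson correlation distance d = 1 - r of the two
groups' mean profiles, and the Euclidean distance of the mean profiles.
The correlation distance lives in [0, 2]; since very distant in-vitro
outgroups inflate absolute intensities, it is the default metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data import GroupMeanMatrix

__all__ = ["DistanceMatrix", "distance_matrix", "read_distance_table"]

METRICS = ("pearson", "euclidean")


@dataclass
class DistanceMatrix:
    """Symmetric matrix of observed distances between labeled groups."""

    labels: list[str]
    values: np.ndarray
    metric: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("distance matrix labels must be unique")
        if self.values.shape != (n, n):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal must be zero")
        if self.values.min() < -1e-9:
            raise ValueError("distances must be non-negative")
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.labels)

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed (i<j) order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.metric)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_phylip(self, path, lower: bool = False, precision: int = 6) -> None:
        """PHYLIP-style distance matrix text (square by default, or lower triangle)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, label in enumerate(self.labels):
                row = self.values[i, :i] if lower else self.values[i]
                cells = " ".join(f"{v:.{precision}f}" for v in row)
                fh.write(f"{label}\t{cells}\n" if cells else f"{label}\n")


def distance_matrix(means: GroupMeanMatrix, metric: str = "pearson") -> DistanceMatrix:
    """Pairwise distances between the group mean profiles.

    ``pearson``: d_ij = 1 - r_ij across the selected genes (requires >=2
    genes and no constant profile). ``euclidean``: standard L2 distance.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; valid: {METRICS}")
    labels = means.groups
    if len(labels) < 2:
        raise ValueError("need at least 2 groups for a distance matrix")
    profiles = means.values  # genes x groups
    if metric == "pearson":
        if profiles.shape[0] < 2:
            raise ValueError("pearson distance needs >=2 genes")
        sd = profiles.std(axis=0)
        flat = [labels[i] for i in np.flatnonzero(sd == 0.0)]
        if flat:
            raise ValueError(
                "constant mean profile (correlation undefined) for group(s): "
                + ", ".join(flat)
            )
        r = np.corrcoef(profiles, rowvar=False)
        d = np.clip(1.0 - r, 0.0, 2.0)
    else:
        d = squareform(pdist(profiles.T, metric="euclidean"))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(labels), d, metric)


def read_distance_table(path, sep: str = "\t") -> DistanceMatrix:
    """Read a square labeled distance matrix written by ``to_dataframe().to_csv``."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return DistanceMatrix(list(df.index.astype(str)), df.to_numpy())
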