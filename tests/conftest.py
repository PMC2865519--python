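import numpy as np
import pandas as pd
import pytest

from phylodiff.build import _incidence
from phylodiff.data import ExpressionMatrix, GroupAnnotation
from phylodiff.distance import DistanceMatrix
from phylodiff.simulate import SimulationSpec, simulate_dataset


@pytest.fixture
def toy_expression() -> ExpressionMatrix:
    """3 genes x 4 samples with hand-listed values."""
    frame = pd.DataFrame(
        {
            "S1": [1.0, 5.0, 2.0],
            "S2": [3.0, 7.0, 2.0],
            "S3": [2.0, 4.0, 8.0],
            "S4": [4.0, 6.0, 10.0],
        },
        index=["G1", "G2", "G3"],
    )
    return ExpressionMatrix(frame)


@pytest.fixture
def toy_annotation() -> GroupAnnotation:
    return GroupAnnotation(
        {"S1": "A", "S2": "A", "S3": "B", "S4": "B"},
        {"A": "subtype", "B": "subtype"},
    )


@pytest.fixture(scope="session")
def sim_small():
    """Small but well-powered synthetic dataset, shared across tests."""
    spec = SimulationSpec(
        n_genes=400, samples_per_group=5, noise_sd=0.4, seed=20240517
    )
    return spec, *simulate_dataset(spec)


def random_unrooted_edges(n: int, rng: np.random.Generator):
    """Random unrooted binary topology on leaves 0..n-1 by random insertion."""
    edges = [(0, n), (1, n), (2, n)]
    for leaf in range(3, n):
        new_internal = n + leaf - 2
        u, v = edges[rng.integers(0, len(edges))]
        edges.remove((u, v))
        edges += [(u, new_internal), (v, new_internal), (leaf, new_internal)]
    return edges


def random_additive_matrix(
    n: int, rng: np.random.Generator, length_range=(0.5, 2.0)
) -> DistanceMatrix:
    """Distance matrix realized exactly by a random tree with distinct lengths."""
    edges = random_unrooted_edges(n, rng)
    A = _incidence(edges, n)
    b = rng.uniform(*length_range, size=len(edges))
    d = A @ b
    M = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    M[iu] = d
    M += M.T
    return DistanceMatrix([chr(65 + i) for i in range(n)], M)


def random_ultrametric_matrix(n: int, rng: np.random.Generator) -> DistanceMatrix:
    """Ultrametric matrix from random agglomeration at increasing heights."""
    heights = np.sort(rng.uniform(0.5, 5.0, size=n - 1))
    clusters = [[i] for i in range(n)]
    M = np.zeros((n, n))
    for h in heights:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                M[a, b] = M[b, a] = 2.0 * h
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return DistanceMatrix([chr(65 + i) for i in range(n)], M)
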