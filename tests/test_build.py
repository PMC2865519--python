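import numpy as np
import pytest

from phylodiff.build import (
    average_percent_sd,
    fit_branch_lengths,
    neighbor_joining,
    search_topology,
    upgma,
)
from phylodiff.distance import DistanceMatrix
from phylodiff.tree import from_newick, path_distance_matrix

from conftest import random_additive_matrix, random_ultrametric_matrix


def dm(labels, rows):
    return DistanceMatrix(list(labels), np.asarray(rows, dtype=float))


ADDITIVE_QUARTET = dm(
    "ABCD",
    [[0, 3, 5, 4], [3, 0, 6, 5], [5, 6, 0, 5], [4, 5, 5, 0]],
)


def pendant_lengths(tree):
    return {n.name: n.length for n in tree.root.walk() if n.is_leaf}


class TestNeighborJoining:
    def test_three_point_formulas(self):
        t = neighbor_joining(dm("ABC", [[0, 3, 4], [3, 0, 5], [4, 5, 0]]))
        assert pendant_lengths(t) == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_additive_quartet_topology_and_lengths(self):
        t = neighbor_joining(ADDITIVE_QUARTET)
        assert t.bipartitions() == {frozenset({"C", "D"})}  # AB|CD oriented away from A
        assert pendant_lengths(t) == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 2.0}
        np.testing.assert_allclose(
            path_distance_matrix(t).values, ADDITIVE_QUARTET.values
        )

    def test_equidistant_taxa_zero_internal_edge(self):
        t = neighbor_joining(dm("ABCD", 2.0 * (1 - np.eye(4))))
        internal = [
            n for n in t.root.walk() if not n.is_leaf and n is not t.root
        ]
        assert internal[0].length == pytest.approx(0.0)
        # first-index tie-break: A and B joined first
        assert {c.name for c in internal[0].children} == {"A", "B"}

    def test_too_few_labels_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(dm("AB", [[0, 1], [1, 0]]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scikit_bio_topology_on_random_matrices(self, seed):
        import warnings

        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(seed)
        n = 6
        noise = rng.uniform(0, 0.05, size=(n, n))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        d = random_additive_matrix(n, rng)
        noisy = DistanceMatrix(d.labels, d.values + noise)
        ours = neighbor_joining(noisy)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            theirs = skbio_nj(SkbioDM(noisy.values, noisy.labels))
        assert ours.bipartitions() == from_newick(str(theirs).strip()).bipartitions()


class TestUpgma:
    def test_ultrametric_triplet(self):
        t = upgma(dm("ABC", [[0, 2, 4], [2, 0, 4], [4, 4, 0]]))
        # A,B join at height 1; C at height 2
        heights = path_distance_matrix(t)
        assert heights.loc("A", "B") == pytest.approx(2.0)
        assert heights.loc("A", "C") == pytest.approx(4.0)
        assert t.rooted

    def test_identical_pair_joined_at_zero(self):
        t = upgma(dm("ABC", [[0, 0, 3], [0, 0, 3], [3, 3, 0]]))
        assert path_distance_matrix(t).loc("A", "B") == 0.0

    def test_four_taxon_merge_heights(self):
        d = dm(
            "ABCD",
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]],
        )
        t = upgma(d)
        np.testing.assert_allclose(path_distance_matrix(t).values, d.values)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_random_ultrametric_matrices(self, seed):
        rng = np.random.default_rng(seed + 50)
        d = random_ultrametric_matrix(6, rng)
        t = upgma(d)
        np.testing.assert_allclose(
            path_distance_matrix(t).reorder(d.labels).values, d.values, atol=1e-9
        )

    def test_matches_scipy_average_linkage_cophenetic(self):
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(9)
        vals = rng.uniform(1, 5, size=(6, 6))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        d = DistanceMatrix(list("ABCDEF"), vals)
        t = upgma(d)
        ours = path_distance_matrix(t).reorder(d.labels).condensed()
        theirs = cophenet(average(squareform(vals)))
        np.testing.assert_allclose(ours, theirs, atol=1e-9)


class TestBranchLengthFit:
    def test_exact_fit_on_generating_topology(self):
        t = from_newick("((A:9,B:9):9,C:9,D:9);")  # right topology, wrong lengths
        fitted, fit = fit_branch_lengths(t, ADDITIVE_QUARTET)
        assert fit.objective == pytest.approx(0.0, abs=1e-15)
        assert fit.apsd == pytest.approx(0.0, abs=1e-6)
        assert pendant_lengths(fitted) == pytest.approx(
            {"A": 1.0, "B": 2.0, "C": 3.0, "D": 2.0}
        )

    def test_wrong_topology_has_positive_objective(self):
        t = from_newick("((A:1,C:1):1,B:1,D:1);")
        _, fit = fit_branch_lengths(t, ADDITIVE_QUARTET)
        assert fit.objective > 1e-3

    def test_equidistant_quartet_substitution_check(self):
        t = from_newick("((A:1,B:1):1,C:1,D:1);")
        fitted, fit = fit_branch_lengths(t, dm("ABCD", 2.0 * (1 - np.eye(4))))
        assert fit.objective == pytest.approx(0.0, abs=1e-12)
        lengths = pendant_lengths(fitted)
        assert lengths == pytest.approx({k: 1.0 for k in "ABCD"}, abs=1e-6)

    def test_zero_distance_strict_mode_errors(self):
        d = dm("ABC", [[0, 0, 1], [0, 0, 1], [1, 1, 0]])
        t = from_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="strict"):
            fit_branch_lengths(t, d, zero_policy="strict")
        fit_branch_lengths(t, d, zero_policy="lenient")  # substitutes min weight


class TestAveragePercentSd:
    def test_perfect_fit_is_zero(self):
        t = from_newick("((A:1,B:2):1,C:3,D:2);")
        assert average_percent_sd(ADDITIVE_QUARTET, t) == pytest.approx(0.0)

    def test_uniform_ten_percent_overestimate(self):
        t = from_newick("((A:1.1,B:2.2):1.1,C:3.3,D:2.2);")
        assert average_percent_sd(ADDITIVE_QUARTET, t) == pytest.approx(10.0)

    def test_hand_computed_three_pair_case(self):
        # relative errors (0.1, -0.2, 0) -> 100*sqrt(0.05/3) ~ 12.91
        d = dm("ABC", [[0, 2, 2], [2, 0, 2], [2, 2, 0]])
        t = from_newick("(A:1.1,B:1.1,C:0.7);")
        # d^T: AB=2.2 (+10%), AC=1.8 (-10%)... craft exactly:
        # AB = 2.2 (+0.1), AC = 1.6 (-0.2), BC = 2.0 (0)
        t = from_newick("(A:0.9,B:1.3,C:0.7);")
        assert average_percent_sd(d, t) == pytest.approx(
            100 * np.sqrt(0.05 / 3), abs=1e-9
        )


class TestSearchTopology:
    def test_wls_selects_generating_quartet(self):
        t, fit = search_topology(ADDITIVE_QUARTET, "wls")
        assert t.bipartitions() == {frozenset({"C", "D"})}
        assert fit.objective == pytest.approx(0.0, abs=1e-15)

    def test_me_selects_generating_quartet(self):
        t, fit = search_topology(ADDITIVE_QUARTET, "me")
        assert t.bipartitions() == {frozenset({"C", "D"})}
        assert fit.objective == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("criterion", ["wls", "me"])
    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_additive_recovery_with_zero_error(self, criterion, n):
        rng = np.random.default_rng(n * 17)
        d = random_additive_matrix(n, rng)
        t, fit = search_topology(d, criterion)
        np.testing.assert_allclose(
            path_distance_matrix(t).reorder(d.labels).values, d.values, atol=1e-7
        )
        assert fit.objective == pytest.approx(0.0, abs=1e-12)
        assert fit.apsd == pytest.approx(0.0, abs=1e-4)

    @pytest.mark.parametrize("seed", range(6))
    def test_heuristic_equals_exhaustive_optimum(self, seed):
        rng = np.random.default_rng(seed + 200)
        d = random_additive_matrix(6, rng)
        noise = rng.uniform(0, 0.15, size=d.values.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        noisy = DistanceMatrix(d.labels, d.values + noise)
        exhaustive, fe = search_topology(noisy, "wls")
        heuristic, fh = search_topology(noisy, "wls", exhaustive_max_leaves=3)
        assert heuristic.canonical_newick() == exhaustive.canonical_newick()
        assert fh.objective == pytest.approx(fe.objective, rel=1e-9)

    def test_search_result_not_worse_than_random_topology(self):
        rng = np.random.default_rng(77)
        d = random_additive_matrix(6, rng)
        noise = rng.uniform(0, 0.3, size=d.values.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        noisy = DistanceMatrix(d.labels, d.values + noise)
        best, fit = search_topology(noisy, "wls")
        # a deliberately arbitrary topology can never beat the search optimum
        arbitrary = from_newick("(((A:1,F:1):1,(B:1,E:1):1):1,C:1,D:1);")
        _, arbitrary_fit = fit_branch_lengths(arbitrary, noisy)
        assert fit.objective <= arbitrary_fit.objective + 1e-12

    def test_too_few_labels_rejected(self):
        with pytest.raises(ValueError):
            search_topology(dm("AB", [[0, 1], [1, 0]]))
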