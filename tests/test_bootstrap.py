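from collections import Counter

import numpy as np
import pytest

from phylodiff.bootstrap import (
    BootstrapSpec,
    draw_replicate,
    majority_consensus,
    rank_from_tree,
    run_bootstrap,
)
from phylodiff.datasets import LIPOSARCOMA_CONSENSUS_NEWICK
from phylodiff.simulate import SimulationSpec, simulate_dataset
from phylodiff.tree import from_newick


class TestDrawReplicate:
    GENES = [f"G{i}" for i in range(50)]
    SAMPLES = {"A": ["a1", "a2", "a3"], "B": ["b1", "b2"]}

    def test_deterministic_given_rng_state(self):
        one = draw_replicate(np.random.default_rng(42), self.GENES, self.SAMPLES)
        two = draw_replicate(np.random.default_rng(42), self.GENES, self.SAMPLES)
        assert one == two

    def test_subset_size_bounds_and_group_sizes(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            genes, resampled = draw_replicate(rng, self.GENES, self.SAMPLES)
            assert 1 <= len(genes) <= 50
            assert len(resampled["A"]) == 3 and len(resampled["B"]) == 2
            assert set(resampled["A"]) <= set(self.SAMPLES["A"])

    def test_subset_size_mean_matches_discrete_uniform(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(101)]
        sizes = [
            len(draw_replicate(rng, genes, self.SAMPLES)[0]) for _ in range(10_000)
        ]
        se = np.sqrt((101**2 - 1) / 12) / np.sqrt(10_000)
        assert abs(np.mean(sizes) - 51.0) <= 3 * se


class TestRunBootstrap:
    def test_replicate_count(self, sim_small):
        _, x, a, truth = sim_small
        genes = truth.genes_of_class("monotone")[:40]
        trees, redraws = run_bootstrap(x, a, genes, BootstrapSpec(replicates=10, seed=3))
        assert len(trees) == 10

    def test_zero_replicates_and_consensus_refusal(self, sim_small):
        _, x, a, truth = sim_small
        genes = truth.genes_of_class("monotone")[:10]
        trees, _ = run_bootstrap(x, a, genes, BootstrapSpec(replicates=0, seed=3))
        assert trees == []
        with pytest.raises(ValueError):
            majority_consensus(trees)

    def test_same_seed_reproduces_trees(self, sim_small):
        _, x, a, truth = sim_small
        genes = truth.genes_of_class("monotone")[:30]
        spec = BootstrapSpec(replicates=5, seed=11)
        t1, _ = run_bootstrap(x, a, genes, spec)
        t2, _ = run_bootstrap(x, a, genes, spec)
        assert [t.to_newick() for t in t1] == [t.to_newick() for t in t2]

    def test_vanishing_noise_gives_identical_topologies(self):
        # noiseless monotone means are linear in the trajectory position, so
        # Euclidean replicate distances are additive for any gene draw (the
        # correlation metric needs >=3 generic genes, which a size-1 or -2
        # draw cannot guarantee)
        spec = SimulationSpec(
            n_genes=200, samples_per_group=3, noise_sd=1e-6, seed=4
        )
        x, a, truth = simulate_dataset(spec)
        genes = truth.genes_of_class("monotone")
        trees, _ = run_bootstrap(
            x, a, genes, BootstrapSpec(replicates=25, seed=5, metric="euclidean")
        )
        keys = {t.canonical_newick() for t in trees}
        assert len(keys) == 1


class TestMajorityConsensus:
    def test_identical_trees_all_supports_100(self):
        trees = [from_newick("((A,B),(C,D),E);") for _ in range(7)]
        result = majority_consensus(trees)
        assert set(result.supports.values()) == {100.0}
        assert result.tree.bipartitions() == trees[0].bipartitions()

    def test_two_thirds_split_retained_with_support(self):
        trees = [
            from_newick("((A,B),C,(D,E));"),
            from_newick("((A,B),D,(C,E));"),
            from_newick("((A,C),B,(D,E));"),
        ]
        result = majority_consensus(trees)
        # {D,E} appears in trees 1 and 3 -> 66.7
        assert result.supports[frozenset({"D", "E"})] == 66.7

    def test_supports_equal_direct_recount(self, sim_small):
        _, x, a, truth = sim_small
        genes = truth.genes_of_class("monotone")[:40]
        trees, _ = run_bootstrap(
            x, a, genes, BootstrapSpec(replicates=20, seed=9, tree_method="nj")
        )
        result = majority_consensus(trees)
        tally = Counter()
        for t in trees:
            for s in t.bipartitions():
                tally[s] += 1
        for split, support in result.supports.items():
            assert support == round(100.0 * tally[split] / len(trees), 1)

    def test_invariant_to_replicate_permutation(self, sim_small):
        _, x, a, truth = sim_small
        genes = truth.genes_of_class("monotone")[:40]
        trees, _ = run_bootstrap(
            x, a, genes, BootstrapSpec(replicates=15, seed=2, tree_method="nj")
        )
        fwd = majority_consensus(trees)
        rev = majority_consensus(trees[::-1])
        assert fwd.supports == rev.supports
        assert fwd.tree.canonical_newick() == rev.tree.canonical_newick()

    def test_differing_leaf_sets_rejected(self):
        trees = [from_newick("((A,B),C,D);"), from_newick("((A,B),C,E);")]
        with pytest.raises(ValueError, match="leaf set"):
            majority_consensus(trees)

    def test_incompatible_half_splits_resolved_deterministically(self):
        # AB|CDE and AC|BDE each appear in exactly half the trees; neither is
        # strict majority, and only one can enter the extended consensus
        trees = [
            from_newick("((A,B),C,(D,E));"),
            from_newick("((A,B),C,(D,E));"),
            from_newick("((A,C),B,(D,E));"),
            from_newick("((A,C),B,(D,E));"),
        ]
        result = majority_consensus(trees)
        assert result.supports[frozenset({"D", "E"})] == 100.0
        half_splits = [s for s, v in result.supports.items() if v == 50.0]
        assert len(half_splits) == 1
        # canonical order: the AB|CDE split is keyed 'C,D,E', AC|BDE 'B,D,E'
        assert half_splits[0] == frozenset({"B", "D", "E"})


class TestRankFromTree:
    def test_caterpillar_order(self):
        t = from_newick("(ROOT,(S1,(S2,(S3,REF))));", rooted=True)
        r = rank_from_tree(t, "ROOT", "REF")
        assert r.tiers == [["S1"], ["S2"], ["S3"]]

    def test_cherry_shares_a_tier(self):
        t = from_newick("(ROOT,(S1,((S2,S3),REF)));", rooted=True)
        r = rank_from_tree(t, "ROOT", "REF")
        assert r.tiers == [["S1"], ["S2", "S3"]]

    def test_works_on_unrooted_input(self):
        t = from_newick("((ROOT,S1),S2,(S3,REF));")
        r = rank_from_tree(t, "ROOT", "REF")
        assert r.flat() == ["S1", "S2", "S3"]

    def test_liposarcoma_consensus_ranking(self):
        t = from_newick(LIPOSARCOMA_CONSENSUS_NEWICK)
        r = rank_from_tree(t, "hMSC", "normal_fat")
        assert r.flat() == [
            "dedifferentiated",
            "pleomorphic",
            "myxoid",
            "round-cell",
            "well-differentiated",
        ]

    def test_missing_labels_rejected(self):
        t = from_newick("(ROOT,(S1,(S2,REF)));", rooted=True)
        with pytest.raises(KeyError):
            rank_from_tree(t, "ROOT", "NOPE")
        with pytest.raises(KeyError):
            rank_from_tree(t, "ROOT", "REF", subtypes=["S1", "S9"])
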