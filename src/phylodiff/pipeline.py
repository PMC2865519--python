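"""End-to-end pipeline driver and the systematic parameter sweep.

``run_pipeline`` executes filter -> group means -> distances -> dual
bootstrap -> consensus -> branch-length fit -> rooting -> ranking and
returns every intermediate artifact plus a manifest (seed, versions,
configuration) for reproducibility.  ``parameter_sweep`` enumerates the
full Cartesian grid of tests x corrections x cutoffs x tree methods x
metrics, keys every cell's consensus by its canonical Newick topology,
and tallies the distinct topologies.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from itertools import product

import pandas as pd

from . import __version__
from .bootstrap import (
    BootstrapSpec,
    ConsensusResult,
    Ranking,
    majority_consensus,
    rank_from_tree,
    run_bootstrap,
)
from .build import TreeFit, fit_branch_lengths
from .data import AnnotationError, ExpressionMatrix, GroupAnnotation, compute_group_means
from .diffexpr import SelectionConfig, per_gene_test, results_table, select_genes
from .distance import DistanceMatrix, distance_matrix
from .tree import PhyloTree, root_with_outgroup

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "SweepGrid",
    "parameter_sweep",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    test: str = "anova"
    correction: str = "bh"
    alpha: float = 0.01
    metric: str = "pearson"
    tree_method: str = "wls"
    replicates: int = 10_000
    seed: int = 0
    root_label: str | None = None  # default: the role=root_outgroup group
    ref_label: str | None = None  # default: the role=differentiated_reference group
    exhaustive_max_leaves: int = 8


@dataclass
class PipelineResult:
    selected_genes: list[str]
    test_table: pd.DataFrame
    distances: DistanceMatrix
    consensus: ConsensusResult
    consensus_fitted: PhyloTree
    rooted: PhyloTree
    ranking: Ranking
    fit: TreeFit
    redraws: int
    manifest: dict

    @property
    def n_selected(self) -> int:
        return len(self.selected_genes)


def _resolve_labels(a: GroupAnnotation, config: PipelineConfig) -> tuple[str, str]:
    root = config.root_label or a.root_outgroup
    ref = config.ref_label or a.differentiated_reference
    if root is None:
        raise AnnotationError(
            "no root outgroup: designate a group with role root_outgroup "
            "or set config.root_label"
        )
    if ref is None:
        raise AnnotationError(
            "no differentiated reference: designate a group with role "
            "differentiated_reference or set config.ref_label"
        )
    for label in (root, ref):
        if label not in a.groups:
            raise AnnotationError(f"label {label!r} is not an annotated group")
    return root, ref


def run_pipeline(
    x: ExpressionMatrix, a: GroupAnnotation, config: PipelineConfig
) -> PipelineResult:
    """Run the full differentiation-phylogeny pipeline."""
    a.validate_against(x)
    root, ref = _resolve_labels(a, config)  # validate before any heavy work

    sel_cfg = SelectionConfig(config.test, config.correction, config.alpha)
    results = per_gene_test(x, a, config.test)
    table = results_table(results, sel_cfg)
    selected = select_genes(results, sel_cfg)
    if not selected:
        raise AnnotationError(
            "no differentially expressed genes selected; tree construction refused"
        )

    means = compute_group_means(x, a, selected)
    distances = distance_matrix(means, config.metric)

    spec = BootstrapSpec(
        replicates=config.replicates,
        seed=config.seed,
        tree_method=config.tree_method,
        metric=config.metric,
        exhaustive_max_leaves=config.exhaustive_max_leaves,
    )
    trees, redraws = run_bootstrap(x, a, selected, spec)
    consensus = majority_consensus(trees)
    fitted, fit = fit_branch_lengths(consensus.tree, distances)
    # carry the consensus supports onto the fitted tree's branches
    for split, clade_support in consensus.tree.bipartitions(with_support=True).items():
        for s, fitted_clade in _split_clades(fitted).items():
            if s == split:
                fitted_clade.support = clade_support
    rooted = root_with_outgroup(fitted, root)
    ranking = rank_from_tree(rooted, root, ref, subtypes=a.subtypes)

    import numpy
    import scipy

    manifest = {
        "config": {k: v for k, v in asdict(config).items() if not callable(v)},
        "root_label": root,
        "ref_label": ref,
        "n_genes_tested": len(results),
        "n_genes_selected": len(selected),
        "n_redraws": redraws,
        "versions": {
            "phylodiff": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    return PipelineResult(
        selected_genes=selected,
        test_table=table,
        distances=distances,
        consensus=consensus,
        consensus_fitted=fitted,
        rooted=rooted,
        ranking=ranking,
        fit=fit,
        redraws=redraws,
        manifest=manifest,
    )


def _split_clades(tree: PhyloTree):
    """Map each nontrivial split to the clade carrying its branch."""
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    out = {}

    def collect(node):
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(collect(c) for c in node.children))
        side = below if ref not in below else all_leaves - below
        if 2 <= len(side) <= len(all_leaves) - 2:
            out[side] = node
        return below

    for child in tree.root.children:
        collect(child)
    return out


# ---------------------------------------------------------------------------
# Parameter sweep


@dataclass
class SweepGrid:
    """Cartesian grid of pipeline options for the systematic comparison."""

    tests: list[str] = field(default_factory=lambda: ["anova", "kruskal_wallis", "welch"])
    corrections: list[str] = field(default_factory=lambda: ["bh", "holm"])
    alphas: list[float] = field(default_factory=lambda: [0.01, 0.05])
    tree_methods: list[str] = field(default_factory=lambda: ["wls", "me", "nj", "upgma"])
    metrics: list[str] = field(default_factory=lambda: ["pearson", "euclidean"])
    #: extra tree-reconstruction methods (name -> DistanceMatrix -> PhyloTree);
    #: a None value reserves the slot for grid-size accounting only.
    plugin_methods: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        n_methods = len(self.tree_methods) + len(self.plugin_methods)
        return (
            len(self.tests)
            * len(self.corrections)
            * len(self.alphas)
            * n_methods
            * len(self.metrics)
        )

    def cells(self):
        methods = list(self.tree_methods) + list(self.plugin_methods.items())
        yield from product(self.tests, self.corrections, self.alphas, methods, self.metrics)


def parameter_sweep(
    grid: SweepGrid,
    x: ExpressionMatrix,
    a: GroupAnnotation,
    base: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the pipeline for every grid cell.

    Returns (per-cell table, topology summary).  Cells with identical
    consensus topologies collapse onto the same canonical-Newick key in
    the summary.
    """
    base = base or PipelineConfig(replicates=100)
    rows = []
    for test, correction, alpha, method, metric in grid.cells():
        if isinstance(method, tuple):
            name, fn = method
            if fn is None:
                raise ValueError(
                    f"plugin method {name!r} has no callable; provide one to sweep"
                )
            method_name, tree_method = name, fn
        else:
            method_name, tree_method = method, method
        config = PipelineConfig(
            test=test,
            correction=correction,
            alpha=alpha,
            metric=metric,
            tree_method=tree_method,
            replicates=base.replicates,
            seed=base.seed,
            root_label=base.root_label,
            ref_label=base.ref_label,
            exhaustive_max_leaves=base.exhaustive_max_leaves,
        )
        cell = {
            "test": test,
            "correction": correction,
            "alpha": alpha,
            "tree_method": method_name,
            "metric": metric,
        }
        try:
            result = run_pipeline(x, a, config)
        except AnnotationError as exc:
            # an empty gene selection is a per-cell outcome (warning-grade in
            # the filter contract), not a reason to abandon the other cells
            cell.update(n_selected=0, topology=None, ranking=None, error=str(exc))
            rows.append(cell)
            continue
        cell.update(
            n_selected=result.n_selected,
            topology=result.consensus.tree.canonical_newick(),
            ranking=str(result.ranking),
            error=None,
        )
        rows.append(cell)
    table = pd.DataFrame(rows)
    summary = (
        table.dropna(subset=["topology"])
        .groupby("topology")
        .agg(
            n_configs=("topology", "size"),
            rankings=("ranking", lambda s: sorted(set(s))),
        )
        .reset_index()
        .sort_values("n_configs", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return table, summary
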