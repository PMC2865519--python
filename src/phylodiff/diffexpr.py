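"""Per-gene multi-group differential-expression testing and gene selection.

Genes that are differentially expressed in at least one tumor subtype are
identified with a one-way ANOVA (default), Welch's heteroscedastic one-way
test, or the tie-corrected Kruskal-Wallis test, followed by
Benjamini-Hochberg (FDR) or Holm (FWER) multiple-testing correction.
Testing is restricted to groups with role ``subtype``: outgroup, reference
and auxiliary samples never enter the statistic, since they are added to
the analysis only afterwards for rooting and ranking.

Constant ("degenerate") genes, whose within- and between-group variance is
both zero, receive p = 1 and are never selected: their 0/0 F statistic is
undefined and exclusion is the conservative choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import ExpressionMatrix, GroupAnnotation, AnnotationError

__all__ = [
    "GeneTestResult",
    "SelectionConfig",
    "TEST_METHODS",
    "adjust_pvalues",
    "expected_false_positives",
    "per_gene_test",
    "results_table",
    "select_genes",
]

TEST_METHODS = ("anova", "welch", "kruskal_wallis")
CORRECTIONS = ("bh", "holm")


@dataclass
class GeneTestResult:
    gene_id: str
    method: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    degenerate: bool = False


@dataclass
class SelectionConfig:
    """Test/correction/cutoff configuration for gene selection.

    ``alpha`` is the adjusted-p cutoff (FDR level for BH, FWER level for
    Holm); selection is strict (< alpha). ``scope`` optionally restricts the
    subtype groups entering the test.
    """

    test: str = "anova"
    correction: str = "bh"
    alpha: float = 0.01
    scope: list[str] | None = None

    def __post_init__(self) -> None:
        if self.test not in TEST_METHODS:
            raise ValueError(f"unknown test {self.test!r}; valid: {TEST_METHODS}")
        if self.correction not in CORRECTIONS:
            raise ValueError(
                f"unknown correction {self.correction!r}; valid: {CORRECTIONS}"
            )
        if not 0.0 < self.alpha < 1.0 and self.alpha != 1.0:
            raise ValueError("alpha must lie in (0, 1]")


def _group_blocks(
    x: ExpressionMatrix, a: GroupAnnotation, groups: list[str] | None
) -> tuple[list[str], list[np.ndarray]]:
    a.validate_against(x)
    subtypes = groups if groups is not None else a.require_subtypes()
    if len(subtypes) < 2:
        raise AnnotationError("differential testing needs >=2 subtype groups")
    blocks = [x.frame[a.samples_of(g)].to_numpy() for g in subtypes]
    return subtypes, blocks


def _degenerate_mask(blocks: list[np.ndarray]) -> np.ndarray:
    all_vals = np.hstack(blocks)
    grand = all_vals.mean(axis=1)
    sst = ((all_vals - grand[:, None]) ** 2).sum(axis=1)
    # rounding floor: identical floats can leave ~1e-34 residual sums of squares
    thresh = all_vals.shape[1] * (1e-12 * (1.0 + np.abs(grand))) ** 2
    return sst <= thresh


def _anova(blocks: list[np.ndarray]):
    k = len(blocks)
    ns = np.array([b.shape[1] for b in blocks], dtype=float)
    n_total = ns.sum()
    means = np.column_stack([b.mean(axis=1) for b in blocks])  # G x k
    grand = np.hstack(blocks).mean(axis=1)
    ssb = (ns[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    ssw = np.zeros_like(ssb)
    for b, m in zip(blocks, means.T):
        ssw += ((b - m[:, None]) ** 2).sum(axis=1)
    df1, df2 = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df1) / (ssw / df2)
    p = stats.f.sf(f, df1, df2)
    p = np.where(np.isinf(f), 0.0, p)
    return f, (float(df1), float(df2)), p


def _welch(blocks: list[np.ndarray]):
    """Welch's unequal-variance one-way ANOVA (heteroscedastic k-group test)."""
    k = len(blocks)
    ns = np.array([b.shape[1] for b in blocks], dtype=float)
    means = np.column_stack([b.mean(axis=1) for b in blocks])
    variances = np.column_stack([b.var(axis=1, ddof=1) for b in blocks])
    variances = np.maximum(variances, 1e-300)  # zero-variance group: let F blow up
    w = ns[None, :] / variances  # G x k
    w_sum = w.sum(axis=1)
    mw = (w * means).sum(axis=1) / w_sum
    a_num = (w * (means - mw[:, None]) ** 2).sum(axis=1) / (k - 1)
    tmp = ((1.0 - w / w_sum[:, None]) ** 2 / (ns - 1.0)[None, :]).sum(axis=1)
    f = a_num / (1.0 + 2.0 * (k - 2.0) / (k**2 - 1.0) * tmp)
    df2 = (k**2 - 1.0) / (3.0 * tmp)
    p = stats.f.sf(f, k - 1, df2)
    return f, k - 1, df2, p


def per_gene_test(
    x: ExpressionMatrix,
    a: GroupAnnotation,
    method: str = "anova",
    groups: list[str] | None = None,
) -> list[GeneTestResult]:
    """Test every gene for differential expression across the subtype groups.

    Returns one :class:`GeneTestResult` per gene, in matrix row order.
    """
    if method not in TEST_METHODS:
        raise ValueError(f"unknown test method {method!r}; valid: {TEST_METHODS}")
    subtypes, blocks = _group_blocks(x, a, groups)
    if method in ("anova", "welch"):
        for g, b in zip(subtypes, blocks):
            if b.shape[1] < 2:
                raise AnnotationError(
                    f"group {g!r} has {b.shape[1]} sample(s); {method} needs >=2"
                )
    degenerate = _degenerate_mask(blocks)
    genes = x.gene_ids
    results: list[GeneTestResult] = []

    if method == "anova":
        f, df, p = _anova(blocks)
        for i, g in enumerate(genes):
            if degenerate[i]:
                results.append(GeneTestResult(g, method, 0.0, df, 1.0, True))
            else:
                results.append(GeneTestResult(g, method, float(f[i]), df, float(p[i])))
    elif method == "welch":
        f, df1, df2, p = _welch(blocks)
        for i, g in enumerate(genes):
            if degenerate[i]:
                results.append(GeneTestResult(g, method, 0.0, (float(df1), 0.0), 1.0, True))
            else:
                results.append(
                    GeneTestResult(
                        g, method, float(f[i]), (float(df1), float(df2[i])), float(p[i])
                    )
                )
    else:  # kruskal_wallis
        k = len(blocks)
        df = (float(k - 1),)
        for i, g in enumerate(genes):
            if degenerate[i]:
                results.append(GeneTestResult(g, method, 0.0, df, 1.0, True))
                continue
            try:
                h, p = stats.kruskal(*[b[i] for b in blocks])
            except ValueError:  # all values identical despite mask tolerance
                results.append(GeneTestResult(g, method, 0.0, df, 1.0, True))
                continue
            results.append(GeneTestResult(g, method, float(h), df, float(p)))
    return results


def adjust_pvalues(p, correction: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up or Holm step-down adjusted p-values.

    Output order matches input order; values are monotone-enforced and
    capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    if correction not in CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}; valid: {CORRECTIONS}")
    if p.size == 0:
        return p
    method = "fdr_bh" if correction == "bh" else "holm"
    return multipletests(p, method=method)[1]


def select_genes(results: list[GeneTestResult], cfg: SelectionConfig) -> list[str]:
    """Genes whose adjusted p-value is < alpha, in input order.

    An empty selection emits a warning (tree building will then refuse)
    rather than raising.
    """
    adjusted = adjust_pvalues([r.p_value for r in results], cfg.correction)
    selected = [
        r.gene_id
        for r, q in zip(results, adjusted)
        if not r.degenerate and q < cfg.alpha
    ]
    if not selected:
        warnings.warn(
            f"no genes pass {cfg.correction} < {cfg.alpha}; downstream tree "
            "construction will refuse an empty gene set"
        )
    return selected


def results_table(results: list[GeneTestResult], cfg: SelectionConfig):
    """Tabular view (gene_id, statistic, p, p_adjusted, selected) for reporting."""
    import pandas as pd

    adjusted = adjust_pvalues([r.p_value for r in results], cfg.correction)
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": adjusted,
            "selected": [
                int(not r.degenerate and q < cfg.alpha)
                for r, q in zip(results, adjusted)
            ],
            "degenerate": [int(r.degenerate) for r in results],
        }
    )


def expected_false_positives(n_discoveries: int, q: float) -> float:
    """Expected number of false positives among n discoveries at FDR level q."""
    return n_discoveries * q
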