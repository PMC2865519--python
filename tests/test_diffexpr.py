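import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phylodiff.data import AnnotationError, ExpressionMatrix, GroupAnnotation
from phylodiff.diffexpr import (
    SelectionConfig,
    adjust_pvalues,
    expected_false_positives,
    per_gene_test,
    select_genes,
)


def matrix_from_groups(groups: dict[str, list[list[float]]]):
    """Build (ExpressionMatrix, GroupAnnotation) from {group: rows-per-gene}."""
    sample_to_group = {}
    cols = {}
    for g, rows in groups.items():
        arr = np.asarray(rows, dtype=float)
        for j in range(arr.shape[1]):
            sid = f"{g}_{j}"
            sample_to_group[sid] = g
            cols[sid] = arr[:, j]
    n_genes = len(next(iter(groups.values())))
    frame = pd.DataFrame(cols, index=[f"G{i}" for i in range(n_genes)])
    return ExpressionMatrix(frame), GroupAnnotation(sample_to_group)


class TestPerGeneTest:
    def test_anova_hand_example(self):
        # groups {1,2,3} and {4,5,6}: SSB=13.5, SSW=4, F = 13.5/1 = 13.5
        x, a = matrix_from_groups({"A": [[1, 2, 3]], "B": [[4, 5, 6]]})
        (r,) = per_gene_test(x, a, "anova")
        assert r.statistic == pytest.approx(13.5)
        assert r.df == (1.0, 4.0)
        assert r.p_value == pytest.approx(stats.f.sf(13.5, 1, 4))

    def test_kruskal_wallis_hand_example(self):
        # ranks 1,2 | 3,4: R1=3, R2=7, H = 2.4
        x, a = matrix_from_groups({"A": [[1, 2]], "B": [[3, 4]]})
        (r,) = per_gene_test(x, a, "kruskal_wallis")
        assert r.statistic == pytest.approx(2.4)

    def test_constant_gene_degenerate_p_one(self):
        x, a = matrix_from_groups({"A": [[2.5, 2.5]], "B": [[2.5, 2.5]]})
        for method in ("anova", "welch", "kruskal_wallis"):
            (r,) = per_gene_test(x, a, method)
            assert r.degenerate and r.p_value == 1.0

    def test_two_group_anova_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(5)
        rows_a = rng.normal(size=(30, 6)).tolist()
        rows_b = rng.normal(0.4, size=(30, 8)).tolist()
        x, a = matrix_from_groups({"A": rows_a, "B": rows_b})
        results = per_gene_test(x, a, "anova")
        for i, r in enumerate(results):
            t, p = stats.ttest_ind(rows_a[i], rows_b[i], equal_var=True)
            assert r.statistic == pytest.approx(t**2, rel=1e-10)
            assert r.p_value == pytest.approx(p, rel=1e-10)

    def test_welch_matches_unequal_variance_t_for_two_groups(self):
        rng = np.random.default_rng(6)
        rows_a = rng.normal(size=(20, 5)).tolist()
        rows_b = rng.normal(0.3, 2.0, size=(20, 9)).tolist()
        x, a = matrix_from_groups({"A": rows_a, "B": rows_b})
        results = per_gene_test(x, a, "welch")
        for i, r in enumerate(results):
            t, p = stats.ttest_ind(rows_a[i], rows_b[i], equal_var=False)
            assert r.statistic == pytest.approx(t**2, rel=1e-9)
            assert r.p_value == pytest.approx(p, rel=1e-9)

    def test_kruskal_matches_scipy_three_groups(self):
        rng = np.random.default_rng(7)
        g = {k: rng.normal(size=(10, 4)).tolist() for k in ("A", "B", "C")}
        x, a = matrix_from_groups(g)
        results = per_gene_test(x, a, "kruskal_wallis")
        for i, r in enumerate(results):
            h, p = stats.kruskal(g["A"][i], g["B"][i], g["C"][i])
            assert r.statistic == pytest.approx(h)
            assert r.p_value == pytest.approx(p)

    def test_non_subtype_samples_excluded_from_statistic(self):
        # outgroup differs wildly; subtypes identical distributions
        x, a = matrix_from_groups(
            {"A": [[1.0, 1.1, 0.9]], "B": [[1.05, 0.95, 1.0]]}
        )
        a2 = GroupAnnotation(
            dict(a.sample_to_group) | {"O_0": "OUT", "O_1": "OUT"},
            {"A": "subtype", "B": "subtype", "OUT": "root_outgroup"},
        )
        frame = x.frame.copy()
        frame["O_0"] = 100.0
        frame["O_1"] = 101.0
        (r,) = per_gene_test(ExpressionMatrix(frame), a2, "anova")
        assert r.p_value > 0.5

    def test_small_group_rejected_for_anova(self):
        x, a = matrix_from_groups({"A": [[1.0]], "B": [[2.0, 3.0]]})
        with pytest.raises(AnnotationError, match="'A'"):
            per_gene_test(x, a, "anova")

    def test_unknown_method_rejected(self, toy_expression, toy_annotation):
        with pytest.raises(ValueError, match="ttest"):
            per_gene_test(toy_expression, toy_annotation, "ttest")


def bh_oracle(p):
    """Step-up BH by direct definition (independent of statsmodels)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def holm_oracle(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order, start=1):
        running = max(running, min(1.0, p[i] * (m - rank + 1)))
        adj[i] = running
    return adj


class TestAdjustPvalues:
    def test_bh_hand_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.04, 0.03, 0.002], "bh"),
            [0.02, 0.04, 0.04, 0.008],
        )

    def test_holm_hand_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.04], "holm"), [0.03, 0.04, 0.04]
        )

    def test_equal_inputs_unchanged_under_bh(self):
        np.testing.assert_allclose(adjust_pvalues([0.5] * 3, "bh"), [0.5] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.1, 1.5], "bh")

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40),
        st.sampled_from(["bh", "holm"]),
    )
    def test_matches_independent_oracle_and_bounds(self, p, correction):
        adj = adjust_pvalues(p, correction)
        oracle = bh_oracle(p) if correction == "bh" else holm_oracle(p)
        np.testing.assert_allclose(adj, oracle, atol=1e-12)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()


class TestSelectGenes:
    def _results(self, pvals):
        x, a = matrix_from_groups(
            {"A": [[1, 2]] * len(pvals), "B": [[3, 4]] * len(pvals)}
        )
        rs = per_gene_test(x, a, "anova")
        for r, p in zip(rs, pvals):
            r.p_value = p
        return rs

    def test_threshold_is_strict(self):
        # adjusted values equal raw here (already monotone worst-case check
        # via alpha=1 separately); craft raw p so BH-adjusted are known
        rs = self._results([0.001, 0.5, 0.002])
        selected = select_genes(rs, SelectionConfig(alpha=0.01))
        assert selected == ["G0", "G2"]

    def test_alpha_one_selects_all_nondegenerate(self):
        rs = self._results([0.3, 0.9, 0.5])
        assert len(select_genes(rs, SelectionConfig(alpha=1.0))) == 3

    def test_empty_selection_warns(self):
        rs = self._results([0.9, 0.95])
        with pytest.warns(UserWarning, match="no genes"):
            assert select_genes(rs, SelectionConfig(alpha=0.01)) == []


def test_pure_null_false_discovery_proportion_controlled():
    """Mean realized FDP under the global null stays near the nominal level.

    1000 null genes, 3 groups x 5 samples, BH at q=0.01, 40 replicates
    (quick check; the 200-replicate version runs in the acceptance suite).
    """
    rng = np.random.default_rng(2024)
    fdps = []
    for _ in range(40):
        data = {g: rng.normal(size=(1000, 5)).tolist() for g in ("A", "B", "C")}
        x, a = matrix_from_groups(data)
        rs = per_gene_test(x, a, "anova")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_genes(rs, SelectionConfig(alpha=0.01))
        fdps.append(1.0 if sel else 0.0)
    assert np.mean(fdps) <= 0.05


def test_expected_false_positive_count():
    assert expected_false_positives(11105, 0.01) == pytest.approx(111.05)
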