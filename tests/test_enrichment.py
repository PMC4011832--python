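import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from orqprofiler.copy_number_calling import call_expression
from orqprofiler.core_model import load_table2_fixture
from orqprofiler.enrichment_compare import (
    ContingencyTable2x2,
    NONFUNCTIONAL_SPLIT,
    OverlapSpec,
    SummaryStats,
    annotation_enrichment,
    deorphanized_contingency,
    fisher_exact_2x2,
    hypergeom_overlap,
    nonfunctional_contingency,
    spearman,
    welch_from_summary,
)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def oracle_fisher_two_sided(a, b, c, d):
    """Direct enumeration over all tables with the observed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def point_prob(x):
        return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                / math.comb(n, row1))

    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    p_obs = point_prob(a)
    return sum(point_prob(x) for x in range(lo, hi + 1)
               if point_prob(x) <= p_obs * (1 + 1e-9))


def oracle_hypergeom_upper(N, K, n, x):
    return sum(math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
               for i in range(x, min(K, n) + 1))


class TestFisherExact:
    def test_printed_deorphanized_table(self):
        p, odds = fisher_exact_2x2([[43, 230], [4, 78]])
        assert round(p, 3) == 0.009
        assert p == pytest.approx(oracle_fisher_two_sided(43, 230, 4, 78), rel=1e-9)

    def test_printed_nonfunctional_table(self):
        p, _ = fisher_exact_2x2([[31, 242], [21, 61]])
        assert round(p, 3) == 0.002

    def test_degenerate_margin(self):
        p, odds = fisher_exact_2x2([[0, 10], [0, 10]])
        assert p == pytest.approx(1.0)
        assert math.isnan(odds)

    def test_small_full_enumeration(self):
        p, _ = fisher_exact_2x2([[2, 1], [1, 2]])
        assert p == pytest.approx(oracle_fisher_two_sided(2, 1, 1, 2), rel=1e-12)
        assert p == pytest.approx(1.0)  # symmetric table, all tables as unlikely

    def test_agrees_with_scipy(self):
        # independent library route for the minimum-likelihood rule
        for table in ([[43, 230], [4, 78]], [[31, 242], [21, 61]], [[8, 2], [1, 5]]):
            p_ours, _ = fisher_exact_2x2(table)
            p_scipy = stats.fisher_exact(table, alternative="two-sided")[1]
            assert p_ours == pytest.approx(p_scipy, rel=1e-8)

    def test_transpose_invariance(self):
        p1, _ = fisher_exact_2x2([[43, 230], [4, 78]])
        p2, _ = fisher_exact_2x2([[43, 4], [230, 78]])
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_one_sided_alternatives(self):
        p_g, _ = fisher_exact_2x2([[8, 2], [1, 5]], alternative="greater")
        assert p_g == pytest.approx(
            stats.fisher_exact([[8, 2], [1, 5]], "greater")[1], rel=1e-9)
        p_l, _ = fisher_exact_2x2([[8, 2], [1, 5]], alternative="less")
        assert p_l == pytest.approx(
            stats.fisher_exact([[8, 2], [1, 5]], "less")[1], rel=1e-9)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 30))
    def test_matches_enumeration_property(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        p, _ = fisher_exact_2x2([[a, b], [c, d]])
        assert p == pytest.approx(oracle_fisher_two_sided(a, b, c, d), rel=1e-7)


class TestHypergeomOverlap:
    def test_printed_overlap(self):
        p = hypergeom_overlap(OverlapSpec(261, 174, 202, 145))
        assert round(p, 4) == 0.0012

    def test_exact_small_enumeration(self):
        p = hypergeom_overlap(OverlapSpec(10, 5, 4, 3))
        assert p == pytest.approx(55 / 210, rel=1e-12)

    def test_full_overlap_probability_one(self):
        p = hypergeom_overlap(OverlapSpec(5, 5, 5, 5))
        assert p == pytest.approx(1.0)

    def test_min_feasible_gives_one(self):
        spec = OverlapSpec(10, 6, 7, max(0, 6 + 7 - 10))
        assert hypergeom_overlap(spec) == pytest.approx(1.0)

    def test_infeasible_rejected(self):
        with pytest.raises(ValueError):
            OverlapSpec(10, 5, 4, 5)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(1, 30), st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 30))
    def test_matches_enumeration_property(self, N, K, n, x):
        K, n = min(K, N), min(n, N)
        lo, hi = max(0, K + n - N), min(K, n)
        x = lo + x % (hi - lo + 1)
        p = hypergeom_overlap(OverlapSpec(N, K, n, x))
        assert p == pytest.approx(oracle_hypergeom_upper(N, K, n, x), rel=1e-9)


class TestWelch:
    def test_printed_group_comparison(self):
        t, df, p = welch_from_summary(SummaryStats(174, 247, 47),
                                      SummaryStats(48, 115, 52))
        assert round(p, 3) == 0.002
        assert t == pytest.approx(3.20, abs=0.005)
        assert df == pytest.approx(63.6, abs=0.05)

    def test_identical_summaries(self):
        s = SummaryStats(10, 2, 5)
        t, _, p = welch_from_summary(s, s)
        assert t == 0.0
        assert p == 1.0

    def test_zero_variance_equal_means(self):
        t, _, p = welch_from_summary(SummaryStats(3, 0, 5), SummaryStats(3, 0, 5))
        assert (t, p) == (0.0, 1.0)

    def test_agrees_with_scipy_from_samples(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 2, 25)
        sx = SummaryStats(x.mean(), x.std(ddof=1), len(x))
        sy = SummaryStats(y.mean(), y.std(ddof=1), len(y))
        t, df, p = welch_from_summary(sx, sy)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_reduces_to_pooled_t_in_limit(self):
        # s1 == s2 and n1 == n2: Welch df equals pooled df, p matches pooled t
        s1, s2 = SummaryStats(5, 2, 12), SummaryStats(6, 2, 12)
        t, df, p = welch_from_summary(s1, s2)
        assert df == pytest.approx(22.0)
        t_pooled = (5 - 6) / (2 * math.sqrt(2 / 12))
        assert t == pytest.approx(t_pooled)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            SummaryStats(1, -1, 5)
        with pytest.raises(ValueError):
            SummaryStats(1, 1, 1)


class TestSpearman:
    def test_identity(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert rho == pytest.approx(1.0)

    def test_reversal(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_tie_handling_matches_scipy(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0]
        y = [3.0, 1.0, 4.0, 2.0, 5.0]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_exact_p_small_n(self):
        x = [1.0, 2, 3, 4, 5]
        y = [2.0, 1, 4, 3, 5]
        rho, p = spearman(x, y)
        # brute-force enumeration of all 120 rank orderings
        rx = np.array([1, 2, 3, 4, 5], dtype=float)
        ry = stats.rankdata(y)
        obs = np.corrcoef(rx, ry)[0, 1]
        count = sum(
            1 for perm in itertools.permutations(rx)
            if abs(np.corrcoef(perm, ry)[0, 1]) >= abs(obs) - 1e-12)
        assert p == pytest.approx(count / 120)

    def test_large_n_t_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = x + rng.normal(0, 1, size=30)
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_flagged(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestReconstructedTables:
    def test_deorphanized_table_from_fixture(self):
        t2 = load_table2_fixture()
        table = deorphanized_contingency(t2["copies_mean"])
        assert (table.a, table.b, table.c, table.d) == (43, 230, 4, 78)

    def test_nonfunctional_table(self):
        table = nonfunctional_contingency()
        assert (table.a, table.b, table.c, table.d) == (31, 242, 21, 61)

    def test_nonfunctional_split_reproduces_percentages(self):
        a, c = NONFUNCTIONAL_SPLIT
        assert a + c == 52
        assert round(100 * a / 273, 1) == 11.4  # 31/273 = 11.36%
        assert round(100 * c / 82) == 26        # 21/82 = 25.6%
        # no other split comes closer to the printed 11.3% / 25% pair
        def err(a_):
            return abs(100 * a_ / 273 - 11.3) + abs(100 * (52 - a_) / 82 - 25.0)
        assert min(range(53), key=err) == 31


class TestAnnotationEnrichment:
    def test_reconstructed_margins(self, default_panel):
        # cohort engineered to the printed margins: 273 expressed of 355,
        # with 43 of the 47 deorphanized receptors expressed
        from orqprofiler.core_model import Role
        ors = [a for a in default_panel.assays
               if a.role is Role.OR_TARGET and a.assay_id != "OR2A14"]
        t2 = load_table2_fixture().set_index("or_name")
        expressed = set()
        for a in ors:
            if a.deorphanized:
                if t2.at[a.gene_symbol, "copies_mean"] > 5:
                    expressed.add(a.assay_id)
        others = [a.assay_id for a in ors if a.assay_id not in
                  {x.assay_id for x in ors if x.deorphanized}]
        expressed |= set(others[:273 - len(expressed)])
        copies = pd.DataFrame(
            {a.assay_id: [10.0 if a.assay_id in expressed else 1.0] for a in ors})
        calls = call_expression(copies)
        res = annotation_enrichment(calls, default_panel, "deorphanized")
        t = res["table"]
        assert [[t.a, t.b], [t.c, t.d]] == [[43, 230], [4, 78]]
        assert round(res["fisher_p"], 3) == 0.009
        assert res["pct_expressed_annotated"] == pytest.approx(15.8, abs=0.1)
        assert res["pct_nonexpressed_annotated"] == pytest.approx(4.9, abs=0.1)

    def test_missing_annotation_rejected(self, small_panel):
        copies = pd.DataFrame({a: [10.0] for a in small_panel.or_assay_ids()})
        calls = call_expression(copies)
        with pytest.raises(KeyError):
            annotation_enrichment(calls, small_panel, "bogus_flag")

    def test_zero_member_annotation_rejected(self, small_panel):
        copies = pd.DataFrame({a: [10.0] for a in small_panel.or_assay_ids()})
        calls = call_expression(copies)
        with pytest.raises(ValueError):
            annotation_enrichment(calls, small_panel, "deorphanized")

    def test_copy_comparison_welch(self, default_panel):
        rng = np.random.default_rng(0)
        from orqprofiler.core_model import Role
        ors = [a.assay_id for a in default_panel.assays if a.role is Role.OR_TARGET]
        copies = pd.DataFrame(rng.lognormal(2, 1, size=(5, len(ors))), columns=ors)
        calls = call_expression(copies)
        res = annotation_enrichment(calls, default_panel, "deorphanized",
                                    copies=copies)
        assert 0 <= res["copy_comparison"]["p"] <= 1
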