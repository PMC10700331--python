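"""Weight-of-Evidence scoring, category merging and Information Value."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ketogene.association import GenotypeOutcomeTable
from ketogene.exceptions import (
    DegenerateOutcomeError,
    ParameterError,
    UnknownCategoryError,
    ZeroCellError,
)
from ketogene.woe import (
    compute_woe,
    information_value,
    merge_similar,
    woe_score,
)

# Hand-arithmetic WoE oracle for the published counts (goods 928, bads 49):
#   WoE(g) = ln((goods_g/928) / (bads_g/49)) * 100
ORACLE = {
    "CT": math.log((462 / 928) / (23 / 49)) * 100,
    "CC": math.log((385 / 928) / (25 / 49)) * 100,
    "TT": math.log((81 / 928) / (1 / 49)) * 100,
}

positive_tables = st.builds(
    GenotypeOutcomeTable,
    st.lists(st.integers(min_value=1, max_value=500), min_size=6, max_size=6).map(
        lambda v: np.array(v).reshape(2, 3)
    ),
)


class TestComputeWoe:
    def test_hand_arithmetic_oracle_on_study_counts(self, study_table):
        wt = compute_woe(study_table)
        for genotype, expected in ORACLE.items():
            assert wt[genotype].woe == pytest.approx(expected, abs=1e-9)
        # derived magnitudes: TT ~ +145.3, CT ~ +5.9, CC ~ -20.7
        assert round(wt["TT"].woe, 1) == 145.3
        assert round(wt["CT"].woe, 1) == 5.9
        assert round(wt["CC"].woe, 1) == -20.7

    def test_tt_scores_highest_matching_resistance_reading(self, study_table):
        wt = compute_woe(study_table)
        assert wt["TT"].woe > wt["CT"].woe > wt["CC"].woe

    def test_identical_relative_frequencies_give_zero(self):
        table = GenotypeOutcomeTable([[40, 30, 10], [40, 30, 10]])
        wt = compute_woe(table)
        for e in wt.entries:
            assert e.woe == pytest.approx(0.0, abs=1e-12)

    def test_zero_cell_error_policy_names_category(self, study_table):
        table = GenotypeOutcomeTable([[462, 385, 81], [23, 25, 0]])
        with pytest.raises(ZeroCellError, match="TT"):
            compute_woe(table, zero_cell_policy="error")

    def test_zero_cell_continuity_policy_warns_and_computes(self):
        table = GenotypeOutcomeTable([[462, 385, 81], [23, 25, 0]])
        with pytest.warns(UserWarning, match="continuity"):
            wt = compute_woe(table, zero_cell_policy="continuity")
        # margins: goods 928, bads 23 + 25 + 0 = 48
        expected = math.log(((81 + 0.5) / 928) / (0.5 / 48)) * 100
        assert wt["TT"].woe == pytest.approx(expected, abs=1e-9)

    def test_degenerate_outcome_margin_rejected(self):
        with pytest.raises(DegenerateOutcomeError):
            compute_woe(GenotypeOutcomeTable([[10, 10, 10], [0, 0, 0]]))

    @given(positive_tables)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_balance_identity_property(self, table):
        """Sum of (rel_freq_goods - rel_freq_bads) is exactly zero."""
        wt = compute_woe(table)
        assert sum(e.rel_freq_goods - e.rel_freq_bads for e in wt.entries) == pytest.approx(
            0.0, abs=1e-12
        )

    @given(positive_tables)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_woe_order_reverses_empirical_risk_order(self, table):
        wt = compute_woe(table)
        by_woe = sorted(wt.entries, key=lambda e: e.woe)
        risks = [e.bads / (e.goods + e.bads) for e in by_woe]
        assert all(a >= b - 1e-12 for a, b in zip(risks, risks[1:]))


class TestMergeSimilar:
    def test_study_counts_merge_cc_with_ct_at_gap_30(self, study_table):
        merged = merge_similar(compute_woe(study_table), max_gap=30.0)
        categories = {e.category for e in merged.entries}
        assert categories == {"CT+CC", "TT"}
        pooled = merged["CT+CC"]
        assert (pooled.goods, pooled.bads) == (462 + 385, 23 + 25)
        assert pooled.woe == pytest.approx(
            math.log((847 / 928) / (48 / 49)) * 100, abs=1e-9
        )
        assert len(merged.merge_log) == 1

    def test_zero_gap_is_identity_for_distinct_woes(self, study_table):
        wt = compute_woe(study_table)
        merged = merge_similar(wt, max_gap=0.0)
        assert [e.category for e in merged.entries] == ["CT", "CC", "TT"]

    def test_identical_categories_pool_to_shared_woe(self):
        table = GenotypeOutcomeTable([[50, 50, 10], [5, 5, 30]])
        wt = compute_woe(table)
        merged = merge_similar(wt, max_gap=0.0)
        assert len(merged.entries) == 2
        assert merged["CT+CC"].woe == pytest.approx(wt["CT"].woe, abs=1e-9)

    def test_negative_gap_rejected(self, study_table):
        with pytest.raises(ParameterError):
            merge_similar(compute_woe(study_table), max_gap=-1.0)

    @given(positive_tables, st.floats(min_value=0, max_value=400))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_merging_conserves_margins_and_bounds_pooled_woe(self, table, gap):
        wt = compute_woe(table)
        merged = merge_similar(wt, max_gap=gap)
        assert sum(e.goods for e in merged.entries) == wt.total_goods
        assert sum(e.bads for e in merged.entries) == wt.total_bads
        assert sum(e.rel_freq_goods - e.rel_freq_bads for e in merged.entries) == (
            pytest.approx(0.0, abs=1e-12)
        )
        originals = {e.category: e.woe for e in wt.entries}
        for e in merged.entries:
            if e.merged_from:
                members = [originals[m] for m in e.merged_from]
                assert min(members) - 1e-9 <= e.woe <= max(members) + 1e-9


class TestInformationValue:
    def test_independence_table_has_zero_iv(self):
        table = GenotypeOutcomeTable([[40, 30, 10], [40, 30, 10]])
        assert information_value(compute_woe(table)) == pytest.approx(0.0, abs=1e-12)

    def test_term_by_term_oracle_on_study_counts(self, study_table):
        wt = compute_woe(study_table)
        expected = 0.0
        for g, b in ((462, 23), (385, 25), (81, 1)):
            rf_g, rf_b = g / 928, b / 49
            expected += (rf_g - rf_b) * math.log(rf_g / rf_b)
        assert information_value(wt) == pytest.approx(expected, abs=1e-12)

    @given(positive_tables)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_iv_nonnegative_property(self, table):
        assert information_value(compute_woe(table)) >= -1e-12


class TestWoeScore:
    def test_lookup_returns_category_woe(self, study_table):
        wt = compute_woe(study_table)
        assert woe_score("TT", wt) == pytest.approx(ORACLE["TT"], abs=1e-9)

    def test_merged_member_resolves_to_pooled_category(self, study_table):
        merged = merge_similar(compute_woe(study_table), max_gap=30.0)
        assert woe_score("CC", merged) == woe_score("CT", merged)

    def test_unknown_label_raises(self, study_table):
        with pytest.raises(UnknownCategoryError):
            woe_score("GG", compute_woe(study_table))
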