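"""Fisher exact testing against an independent hypergeometric oracle,
BH adjustment, and the target-vs-background fraction summary."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from starpap import (
    ContingencyTable,
    RegionPair,
    bh_adjust,
    compare_fractions,
    compute_kmer_stats,
    fisher_exact,
)


def hypergeom_tail(a, b, c, d):
    """Exact-arithmetic oracle: P(X >= a) for X ~ Hypergeom(margins)."""
    n_pop, k_with, n_draw = a + b + c + d, a + c, a + b
    total = Fraction(0)
    for k in range(a, min(k_with, n_draw) + 1):
        if n_draw - k <= n_pop - k_with:
            total += Fraction(
                comb(k_with, k) * comb(n_pop - k_with, n_draw - k),
                comb(n_pop, n_draw),
            )
    return float(total)


class TestFisher:
    def test_enrichment_tail_matches_frozen_oracle_value(self):
        # oracle: sum_{k=8..10} C(10,k) C(10,10-k) / C(20,10) = 1063/92378
        p = fisher_exact(ContingencyTable(8, 2, 2, 8))
        assert p == pytest.approx(1063 / 92378, abs=1e-15)

    @pytest.mark.parametrize("table", [(10, 0, 10, 0), (0, 10, 10, 0)])
    def test_degenerate_tables_give_p_one(self, table):
        assert fisher_exact(ContingencyTable(*table)) == pytest.approx(1.0)

    def test_all_zero_margins_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(ContingencyTable(0, 0, 0, 0))

    def test_two_sided_at_least_one_sided(self):
        t = ContingencyTable(8, 2, 2, 8)
        assert fisher_exact(t, "two-sided") >= fisher_exact(t, "greater")

    @given(
        a=st.integers(0, 12),
        b=st.integers(0, 12),
        c=st.integers(0, 12),
        d=st.integers(0, 12),
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_oracle_on_random_tables(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_exact(ContingencyTable(a, b, c, d)) == pytest.approx(
            hypergeom_tail(a, b, c, d), abs=1e-12
        )


class TestBhAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.01]) == pytest.approx([0.01])

    def test_step_up_hand_computed(self):
        # q_i = min_{j>=i} p_j * m / j on the sorted p-values
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_empty_in_empty_out(self):
        assert bh_adjust([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])

    @given(
        st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=30)
    )
    @settings(max_examples=100, derandomize=True)
    def test_q_dominates_p_and_sorted_stays_sorted(self, ps):
        qs = bh_adjust(ps)
        assert np.all(qs >= np.asarray(ps) - 1e-15)
        assert np.all(qs <= 1.0 + 1e-15)
        qs_sorted = bh_adjust(sorted(ps))
        assert np.all(np.diff(qs_sorted) >= -1e-15)


def _use_region(seq, gene, use_far=10):
    return RegionPair(
        gene_id=gene,
        use_seq=seq,
        dse_seq="ACGUACGUAC",
        use_far=use_far,
        use_near=use_far - len(seq),
        dse_len=10,
    )


def _groups(n_with_target, n_target, n_with_bg, n_bg):
    with_aua, without = "GGGAUAGGGG", "GGGGGGGGGG"
    target = {
        f"t{i}": [_use_region(with_aua if i < n_with_target else without, f"t{i}")]
        for i in range(n_target)
    }
    bg = {
        f"b{i}": [_use_region(with_aua if i < n_with_bg else without, f"b{i}")]
        for i in range(n_bg)
    }
    return target, bg


class TestCompareFractions:
    def test_fractions_and_oracle_p_for_aua_core(self):
        target, bg = _groups(16, 20, 9, 20)
        df = compare_fractions(target, bg)
        row = df[df.word == "AUA"].iloc[0]
        assert row.target_fraction == pytest.approx(0.80)
        assert row.bg_fraction == pytest.approx(0.45)
        assert row.difference == pytest.approx(0.35)
        # frozen from the exact oracle: P(X >= 16) = 1609/66526
        assert row.p == pytest.approx(1609 / 66526, abs=1e-12)
        assert row.p == pytest.approx(hypergeom_tail(16, 4, 9, 11), abs=1e-12)

    def test_identical_sets_give_zero_difference_and_maximal_p(self):
        target, bg = _groups(10, 20, 10, 20)
        row = compare_fractions(target, bg).iloc[0]
        assert row.difference == 0.0
        assert row.p == pytest.approx(hypergeom_tail(10, 10, 10, 10), abs=1e-12)

    def test_mismatched_window_parameters_rejected(self):
        target, _ = _groups(5, 5, 0, 0)
        bg = {"b0": [_use_region("GGGGGGGGGG", "b0", use_far=12)]}
        with pytest.raises(ValueError, match="window parameters"):
            compare_fractions(target, bg)

    def test_synthetic_cohort_aua_enriched(self, result7):
        df = compare_fractions(result7.target_regions, result7.bg_regions)
        row = df[df.word == "AUA"].iloc[0]
        assert row.target_fraction > row.bg_fraction
        assert row.p < 0.05


def test_compute_kmer_stats_q_values_follow_bh(result7):
    stats = compute_kmer_stats(result7.target_regions, result7.bg_regions)
    ps = [s.p_value for s in stats]
    assert [s.q_value for s in stats] == pytest.approx(list(bh_adjust(ps)))
    assert all(s.q_value >= s.p_value - 1e-15 for s in stats)
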