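"""Unit and property tests for k-mer enumeration, masking, occurrence
counting, PWM construction and positional histograms."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from starpap import (
    KmerStat,
    RegionPair,
    build_pwm,
    distinct_aua_5mers,
    enumerate_aua_5mers,
    enumerate_central_7mers,
    gene_occurrence,
    map_to_7mers,
    mask_pas_like,
    positional_distribution,
    select_frequent,
)

DSE10 = "ACGUACGUAC"


def region(use_seq, use_far=None, use_near=0, gene_id="g"):
    use_far = len(use_seq) if use_far is None else use_far
    return RegionPair(
        gene_id=gene_id,
        use_seq=use_seq,
        dse_seq=DSE10,
        use_far=use_far,
        use_near=use_near,
        dse_len=10,
    )


def brute_force_aua_placements():
    """Independent oracle: scan all 4^5 words for AUA substrings."""
    found = []
    for chars in product("ACGU", repeat=5):
        word = "".join(chars)
        for off in range(3):
            if word[off : off + 3] == "AUA":
                found.append((word, off))
    return found


class TestEnumeration:
    def test_48_placements_and_brute_force_agreement(self):
        placements = enumerate_aua_5mers()
        assert len(placements) == 48
        assert {(p.word, p.offset) for p in placements} == set(
            brute_force_aua_placements()
        )

    def test_one_word_admits_two_offsets(self):
        placements = enumerate_aua_5mers()
        words = [p.word for p in placements]
        assert len(set(words)) == len(words) - 1 == 47
        assert {p.offset for p in placements if p.word == "AUAUA"} == {0, 2}
        assert distinct_aua_5mers() == sorted(set(words))

    def test_deterministic_order(self):
        placements = enumerate_aua_5mers()
        assert [(p.offset, p.word) for p in placements] == sorted(
            (p.offset, p.word) for p in placements
        )

    def test_central_7mers(self):
        words = [p.word for p in enumerate_central_7mers()]
        assert len(words) == 256 == len(set(words))
        assert all(w[2:5] == "AUA" for w in words)
        assert "CGAUAGG" in words
        assert "GAUAUAC" not in words  # central triplet is UAU
        assert words == sorted(words)


class TestMasking:
    def test_exact_pas_masked(self):
        r = region("GGG" + "AAUAAA" + "CCCC")
        masked = mask_pas_like(r)
        assert masked.use_seq == "GGG" + "NNNNNN" + "CCCC"

    def test_no_match_unchanged(self):
        r = region("G" * 20)
        assert mask_pas_like(r).use_seq == r.use_seq

    def test_hamming_distance_one_variant(self):
        r = region("CC" + "AAUAUA" + "GG")
        assert "N" in mask_pas_like(r, max_mismatch=1).use_seq
        assert mask_pas_like(r, max_mismatch=0).use_seq == r.use_seq

    @given(st.text(alphabet="ACGU", min_size=10, max_size=60))
    @settings(max_examples=60, derandomize=True)
    def test_masking_never_increases_occurrences(self, seq):
        r = region(seq)
        masked = mask_pas_like(r)
        for word in ("AUA", "AAUAA", "GAUAC"):
            before = sum(
                seq[i : i + len(word)] == word for i in range(len(seq))
            )
            after = sum(
                masked.use_seq[i : i + len(word)] == word for i in range(len(seq))
            )
            assert after <= before


class TestGeneOccurrence:
    def test_gene_level_fraction(self):
        genes = {
            "g1": [region("GGAUACG")],
            "g2": [region("CCCCCCC")],
            "g3": [region("AGAUACA")],
        }
        assert gene_occurrence("GAUAC", genes) == (2, 3, pytest.approx(2 / 3))

    def test_absent_word(self):
        genes = {f"g{i}": [region("CCCCCCC")] for i in range(4)}
        assert gene_occurrence("GAUAC", genes) == (0, 4, 0.0)

    def test_two_hits_in_one_gene_count_once(self):
        genes = {"g1": [region("GAUACGAUAC")]}
        assert gene_occurrence("GAUAC", genes)[0] == 1

    def test_or_over_multiple_sites(self):
        genes = {"g1": [region("CCCCCCC"), region("GGAUACG")]}
        assert gene_occurrence("GAUAC", genes)[0] == 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            gene_occurrence("GAUAC", {})


def _stat(word, frac):
    n = 100
    return KmerStat(word, int(frac * n), n, 0, n, frac, 0.0)


class TestSelectFrequent:
    def test_strict_threshold_and_sort(self):
        stats = [_stat("AAAUA", 0.80), _stat("CAUAC", 0.55), _stat("GAUAG", 0.56)]
        kept = select_frequent(stats)
        assert [s.word for s in kept] == ["AAAUA", "GAUAG"]

    def test_lexicographic_tie_break(self):
        kept = select_frequent([_stat("UAUAC", 0.7), _stat("CAUAU", 0.7)])
        assert [s.word for s in kept] == ["CAUAU", "UAUAC"]

    def test_empty(self):
        assert select_frequent([]) == []


class TestMapTo7mers:
    def test_candidates_are_containment_filtered_central_words(self):
        genes = {"g1": [region("CCAUAUACC")]}
        result = map_to_7mers(["AUAUA"], genes)
        expected = {
            p.word for p in enumerate_central_7mers() if "AUAUA" in p.word
        }
        assert {w for w, _ in result} == expected
        counted = dict(result)
        assert "CAUAUAC" not in counted  # not centrally anchored, never a candidate
        assert counted["AUAUACC"] == 1 and counted["CCAUAUA"] == 1

    def test_empty_frequent_set(self):
        assert map_to_7mers([], {"g": [region("ACGUACG")]}) == []


class TestBuildPwm:
    def test_single_word_gives_indicator_columns(self):
        pwm = build_pwm([("CAUAUAC", 1.0)])
        assert pwm.consensus() == "CAUAUAC"
        assert np.all(np.isin(pwm.matrix, [0.0, 1.0]))
        assert np.allclose(pwm.matrix.sum(axis=0), 1.0)

    def test_all_256_central_words_give_uniform_flanks(self):
        pwm = build_pwm([(p.word, 1.0) for p in enumerate_central_7mers()])
        assert np.allclose(pwm.matrix[:, [0, 1, 5, 6]], 0.25)
        # central columns are exact indicators on A, U, A
        a, c, g, u = 0, 1, 2, 3
        assert pwm.matrix[a, 2] == pwm.matrix[u, 3] == pwm.matrix[a, 4] == 1.0

    def test_weighted_average_column(self):
        pwm = build_pwm([("AAUAAAA", 3.0), ("CAUAAAA", 1.0)])
        assert pwm.matrix[0, 0] == pytest.approx(0.75)
        assert pwm.matrix[1, 0] == pytest.approx(0.25)

    def test_pseudocount_smooths(self):
        pwm = build_pwm([("AAAAAAA", 1.0)], pseudocount=1.0)
        assert pwm.matrix[0, 0] == pytest.approx(2 / 5)
        assert pwm.matrix[1, 0] == pytest.approx(1 / 5)

    def test_empty_support_rejected(self):
        with pytest.raises(ValueError):
            build_pwm([])

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            build_pwm([("AAAAAAA", 0.0)])


class TestPositionalDistribution:
    def test_no_occurrences_gives_zero_histogram(self):
        r = region("G" * 100, use_far=150, use_near=50)
        hist = positional_distribution(["ACAUA"], [r], bin_width=10)
        assert hist.counts.sum() == 0 and len(hist.counts) == 10
        assert hist.bin_edges[0] == -150 and hist.bin_edges[-1] == -50

    def test_single_occurrence_midpoint_binned(self):
        # word start index 58 -> midpoint index 60 -> distance -90
        use = "G" * 58 + "ACAUA" + "G" * 37
        r = region(use, use_far=150, use_near=50)
        hist = positional_distribution(["ACAUA"], [r], bin_width=10)
        assert hist.total == 1
        bin_idx = int(np.searchsorted(hist.bin_edges, -90, side="right")) - 1
        assert hist.counts[bin_idx] == 1
        assert hist.mode_center() == -85.0

    def test_bin_width_must_divide_window(self):
        r = region("G" * 100, use_far=150, use_near=50)
        with pytest.raises(ValueError):
            positional_distribution(["ACAUA"], [r], bin_width=7)

    def test_total_equals_occurrence_count(self, result7):
        flat = [r for rs in result7.target_regions.values() for r in rs]
        hist = positional_distribution(result7.frequent_words, flat)
        n = sum(
            len([i for i in range(len(r.use_seq)) if r.use_seq[i : i + len(w)] == w])
            for r in flat
            for w in set(result7.frequent_words)
        )
        assert hist.total == n
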