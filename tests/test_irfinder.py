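"""Inverted-repeat discovery and TSD detection against brute force."""

import numpy as np
import pytest

from mulefinder import synthgenome as sg
from mulefinder.alignment import revcomp
from mulefinder.irfinder import Tsd, detect_tsd, find_inverted_repeats

from .oracles import oracle_inverted_repeats, oracle_tsd


def planted(rng, tir_len=150, gap=500, n=5000, identity=1.0):
    bg = sg.random_seq(rng, n)
    tir = sg.random_seq(rng, tir_len)
    arm2 = sg.mutate(tir, round((1 - identity) * tir_len), rng)
    mid = n // 2
    seq = bg[: mid - gap // 2 - tir_len] + tir + bg[mid - gap // 2 : mid + gap // 2]
    left_start = mid - gap // 2 - tir_len
    right_start = len(seq)
    seq += revcomp(arm2) + bg[mid + gap // 2 :]
    return seq, (left_start, left_start + tir_len), (right_start, right_start + tir_len)


def test_perfect_repeat_found_at_truth_coordinates():
    rng = np.random.default_rng(0)
    seq, left, right = planted(rng)
    pairs = find_inverted_repeats(seq)
    assert len(pairs) == 1
    p = pairs[0]
    assert p.identity == 100.0
    # boundaries exact up to chance-matching flank bases
    assert abs(p.left_start - left[0]) <= 2 and abs(p.left_end - left[1]) <= 2
    assert abs(p.right_start - right[0]) <= 2 and abs(p.right_end - right[1]) <= 2


def test_87_percent_arms_detected():
    rng = np.random.default_rng(1)
    seq, left, right = planted(rng, identity=0.87)
    pairs = find_inverted_repeats(seq)
    assert len(pairs) == 1
    assert pairs[0].identity >= 80.0
    assert pairs[0].length >= 100


def test_random_background_empty_and_oracle_agrees():
    rng = np.random.default_rng(2)
    for _ in range(5):
        seq = sg.random_seq(rng, 5000)
        assert find_inverted_repeats(seq) == []
        assert oracle_inverted_repeats(seq) == []


def test_oracle_equivalence_on_planted_repeats():
    rng = np.random.default_rng(3)
    for trial in range(5):
        seq, _, _ = planted(rng, identity=0.9, gap=300 + 100 * trial)
        got = find_inverted_repeats(seq)
        expected = oracle_inverted_repeats(seq)
        assert expected, "oracle should find the planted pair"
        # implementation reports the same repeat as every oracle window
        # (the oracle's longest-qualifying window may pad the arm with
        # threshold-tolerated noise, so compare on the shorter of the two)
        for (ls, le), (rs, re) in expected:
            assert any(
                min(p.left_end, le) - max(p.left_start, ls)
                > 0.8 * min(le - ls, p.length)
                and min(p.right_end, re) - max(p.right_start, rs)
                > 0.8 * min(re - rs, p.length)
                for p in got
            )
        # every report re-scores above thresholds by direct counting
        for p in got:
            a = seq[p.left_start : p.left_end]
            b = revcomp(seq[p.right_start : p.right_end])
            matches = sum(1 for x, y in zip(a, b) if x == y)
            assert p.length >= 100
            assert matches / p.length >= 0.80
            assert matches == p.matches


def test_revcomp_symmetry():
    rng = np.random.default_rng(4)
    seq, _, _ = planted(rng, identity=0.92)
    fwd = find_inverted_repeats(seq)
    rev = find_inverted_repeats(revcomp(seq))
    n = len(seq)
    mirrored = sorted(
        (n - p.right_end, n - p.right_start, n - p.left_end, n - p.left_start)
        for p in rev
    )
    direct = sorted(
        (p.left_start, p.left_end, p.right_start, p.right_end) for p in fwd
    )
    assert direct == mirrored


def test_n_runs_split_search_space():
    rng = np.random.default_rng(5)
    seq, left, right = planted(rng)
    # interpose a 120 bp N run between the arms
    mid = (left[1] + right[0]) // 2
    seq = seq[:mid] + "N" * 120 + seq[mid:]
    assert find_inverted_repeats(seq) == []


def test_max_span_filter():
    rng = np.random.default_rng(6)
    seq, _, _ = planted(rng, gap=3000, n=8000)
    assert find_inverted_repeats(seq, max_span=2000) == []
    assert len(find_inverted_repeats(seq, max_span=20000)) == 1


def test_empty_and_short_input():
    assert find_inverted_repeats("") == []
    assert find_inverted_repeats("ACGT" * 10) == []


class TestDetectTsd:
    def build(self, rng, tsd, elem_len=600, flank=300, jitter=0):
        bg = sg.random_seq(rng, 2 * flank + elem_len)
        elem = sg.random_seq(rng, elem_len)
        seq = bg[:flank] + tsd + elem + tsd + bg[flank + elem_len :]
        lb = flank + len(tsd)
        rb = lb + elem_len
        return seq, lb + jitter, rb - jitter

    def test_perfect_9mer(self):
        rng = np.random.default_rng(7)
        # control the abutting context so no longer direct repeat exists
        bg = sg.random_seq(rng, 1200)
        elem = "C" + sg.random_seq(rng, 598) + "G"
        seq = bg[:300] + "TTTTAAATT" + elem + "TTTTAAATT" + bg[900:]
        scan = detect_tsd(seq, 309, 909)
        assert scan.status == "found"
        assert isinstance(scan.tsd, Tsd)
        assert scan.tsd.sequence == "TTTTAAATT"
        assert scan.tsd.mismatches == 0

    def test_random_flanks_absent_matches_oracle(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(200):
            seq = sg.random_seq(rng, 700)
            scan = detect_tsd(seq, 200, 500)
            expected = oracle_tsd(seq, 200, 500)
            if expected is None:
                assert scan.status == "absent"
            else:
                hits += 1
                assert scan.status == "found"
                assert (
                    scan.tsd.length,
                    scan.tsd.mismatches,
                    scan.tsd.left_start,
                    scan.tsd.right_start,
                ) == expected
        assert hits < 40  # chance hits are possible but must stay rare

    def test_longer_window_wins_at_equal_mismatches(self):
        rng = np.random.default_rng(9)
        # left flank carries GATTACAGATT, right flank a copy with two
        # substitutions in the interior: the best 9-mer and the best
        # 11-mer both carry 2 mismatches, so the 11-mer is returned
        left11 = "GATTACAGATT"
        right11 = "GATAACGGATT"  # mismatches at interior positions 3, 6
        bg = sg.random_seq(rng, 1200)
        elem = "C" + sg.random_seq(rng, 598) + "G"
        seq = bg[:300] + left11 + elem + right11 + bg[900:]
        lb, rb = 311, 911
        scan = detect_tsd(seq, lb, rb)
        assert scan.status == "found"
        assert scan.tsd.length == 11
        assert scan.tsd.mismatches == 2

    def test_insufficient_flank_flagged_distinctly(self):
        seq = "ACGTACGTAC" + "A" * 100 + "ACGTACGTAC"
        scan = detect_tsd(seq, 5, 115)
        assert scan.status == "insufficient_flank"
        assert scan.tsd is None

    def test_oracle_equivalence_random_boundaries(self):
        rng = np.random.default_rng(10)
        for _ in range(300):
            seq = sg.random_seq(rng, 400)
            lb = int(rng.integers(50, 150))
            rb = int(rng.integers(250, 350))
            scan = detect_tsd(seq, lb, rb)
            expected = oracle_tsd(seq, lb, rb)
            if expected is None:
                assert not scan
            else:
                assert scan.status == "found"
                assert (
                    scan.tsd.length,
                    scan.tsd.mismatches,
                    scan.tsd.left_start,
                    scan.tsd.right_start,
                ) == expected
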