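"""Genome scan, element assembly, classification, and reporting."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from mulefinder import synthgenome as sg
from mulefinder.alignment import revcomp
from mulefinder.annotator import (
    TirHit,
    assemble_single_elements,
    best_transposase_score,
    autonomy_threshold,
    classify_candidate,
    element_size,
    family_report,
    find_cargo,
    group_copies,
    scan_genome,
    size_histogram,
    summarize_family_counts,
)
from mulefinder.tirlib import TirFamily


def fam(seq, name="LIB1"):
    return TirFamily(family_id=name, representative=seq, source_identity=100.0)


class TestScanGenome:
    def test_implanted_instance_found_with_orientation(self):
        rng = np.random.default_rng(0)
        rep = sg.random_seq(rng, 120)
        inst = sg.mutate(rep, 18, rng)  # 85% identity
        bg = sg.random_seq(rng, 20_000)
        genome = bg[:5000] + inst + bg[5000:10000] + revcomp(inst) + bg[10000:]
        hits = scan_genome(genome, [fam(rep)])
        assert len(hits) == 2
        fwd, rev = hits
        assert (fwd.strand, rev.strand) == ("+", "-")
        assert abs(fwd.start - 5000) <= 2 and abs(fwd.end - 5120) <= 2
        assert fwd.identity >= 80

    def test_short_fragment_below_min_len_not_reported(self):
        rng = np.random.default_rng(1)
        rep = sg.random_seq(rng, 120)
        bg = sg.random_seq(rng, 10_000)
        genome = bg[:4000] + rep[:40] + bg[4000:]
        assert scan_genome(genome, [fam(rep)]) == []

    def test_empty_library_warns(self):
        with pytest.warns(UserWarning):
            assert scan_genome("ACGT" * 1000, []) == []

    def test_truth_arms_all_hit(self, world):
        # every implanted arm >= 50 bp is recovered by the scan
        hit_intervals = [(h.start, h.end) for h in world.hits]
        for t in world.truths:
            for a in t.arms:
                if a.end - a.start < 50:
                    continue
                assert any(
                    min(a.end, e) - max(a.start, s) >= 0.8 * (a.end - a.start)
                    for s, e in hit_intervals
                )


def make_hit(family, start, end, strand, q_start=0, rep_len=150):
    length = end - start
    return TirHit(
        family=family, start=start, end=end, strand=strand,
        matches=length, q_start=q_start, q_end=q_start + length,
        rep_len=rep_len,
    )


class TestAssembleSingles:
    def test_single_element_with_tsd(self, world):
        singles = [t for t in world.truths if t.architecture == "single"]
        for t in singles:
            e = world.truth_match(t)
            assert e is not None
            assert e.architecture == "single"
            assert e.tsd is not None

    def test_same_orientation_hits_stay_orphans(self):
        rng = np.random.default_rng(2)
        genome = sg.random_seq(rng, 5000)
        hits = [make_hit("L", 1000, 1150, "+"), make_hit("L", 2000, 2150, "+")]
        elements, orphans = assemble_single_elements(hits, genome)
        assert elements == []
        assert len(orphans) == 2

    def test_span_rule_excludes_distant_pair(self):
        rng = np.random.default_rng(3)
        genome = sg.random_seq(rng, 30_000)
        hits = [make_hit("L", 1000, 1150, "+"), make_hit("L", 26_000, 26_150, "-")]
        elements, orphans = assemble_single_elements(hits, genome, max_span=20_000)
        assert elements == []
        assert len(orphans) == 2
        elements, _ = assemble_single_elements(hits, genome, max_span=30_000)
        assert len(elements) == 1


class TestClassification:
    def test_all_architectures_recovered(self, world):
        for t in world.truths:
            e = world.truth_match(t)
            assert e is not None, t.element_id
            assert e.architecture == t.architecture, t.element_id

    def test_multi_tir_elements_always_have_tsd(self, world):
        for e in world.elements:
            if e.architecture != "single":
                assert e.tsd is not None

    def test_internal_tirs_have_no_flanking_tsd(self, world):
        # the hallmark separating tandem TIRs from nested insertion
        from mulefinder.irfinder import detect_tsd

        for e in world.elements:
            for hit, role in e.tirs:
                if role != "internal":
                    continue
                partner_bounds = [h for h, r in e.tirs if r == "internal"]
                lb = min(h.start for h in partner_bounds)
                rb = max(h.end for h in partner_bounds)
                scan = detect_tsd(world.genome, lb, rb)
                assert scan.status != "found" or scan.tsd.mismatches > 0
                break

    def test_cargo_defines_type1_vs_type2(self, world):
        archs = Counter(e.architecture for e in world.elements)
        assert archs["type1"] == 4 and archs["type2"] == 4
        for e in world.elements:
            if e.architecture == "type1":
                assert e.cargo_hits
            if e.architecture == "type2":
                assert not e.cargo_hits

    def test_criterion_checks_direct(self):
        # purpose-built hit sets exercise each filter in isolation
        rng = np.random.default_rng(4)
        genome = sg.random_seq(rng, 60_000)
        left = make_hit("L", 1000, 1150, "+")
        inner_l = make_hit("L", 1250, 1400, "+")
        # criterion 1: span beyond 20 kb
        inner_r = make_hit("L", 24_500, 24_650, "-")
        right = make_hit("L", 24_750, 24_900, "-")
        rec, failed = classify_candidate(
            genome, left, right, [inner_l, inner_r]
        )
        assert rec is None and "span_or_gap" in failed
        # criterion 2: a 45 bp counted TIR
        short = make_hit("L", 1250, 1295, "+", rep_len=150)
        inner_r2 = make_hit("L", 2400, 2550, "-")
        right2 = make_hit("L", 2650, 2800, "-")
        rec, failed = classify_candidate(genome, left, right2, [short, inner_r2])
        assert rec is None and "tir_length" in failed
        # criterion 3: external truncation beyond 15 bp
        trunc_left = make_hit("L", 1000, 1125, "+", q_start=25, rep_len=150)
        rec, failed = classify_candidate(
            genome, trunc_left, right2, [inner_l, inner_r2]
        )
        assert rec is None and "truncation" in failed

    def test_rejected_candidates_recorded(self, world):
        # the assembly writes a reject record for failed candidates
        for r in world.assembly.rejects:
            assert r.failed


class TestGroupCopies:
    def test_partition_matches_truth(self, world):
        group_copies(world.elements, world.genome)
        by_cf = {}
        for t in world.truths:
            e = world.truth_match(t)
            by_cf.setdefault(e.copy_family, set()).add(t.family)
        # each copy family maps to exactly one truth family and vice versa
        assert all(len(v) == 1 for v in by_cf.values())
        assert len(by_cf) == len({t.family for t in world.truths})

    def test_single_element_is_own_family(self):
        rng = np.random.default_rng(5)
        genome = sg.random_seq(rng, 10_000)
        hits = [make_hit("L", 1000, 1150, "+"), make_hit("L", 1900, 2050, "-")]
        elements, _ = assemble_single_elements(hits, genome)
        assert len(elements) == 1
        assign = group_copies(elements, genome)
        assert list(assign.values()) == ["CF01"]

    def test_half_alignable_internals_split(self):
        rng = np.random.default_rng(6)
        tir = sg.random_seq(rng, 150)
        shared = sg.random_seq(rng, 400)
        int_a = shared + sg.random_seq(rng, 400)
        int_b = shared + sg.random_seq(rng, 400)
        bg = sg.random_seq(rng, 10_000)
        genome = (
            bg[:2000] + tir + int_a + revcomp(tir)
            + bg[2000:4000] + tir + int_b + revcomp(tir) + bg[4000:]
        )
        s1 = 2000
        s2 = 2000 + 150 + 800 + 150 + 2000
        hits = [
            make_hit("L", s1, s1 + 150, "+"),
            make_hit("L", s1 + 950, s1 + 1100, "-"),
            make_hit("L", s2, s2 + 150, "+"),
            make_hit("L", s2 + 950, s2 + 1100, "-"),
        ]
        elements, _ = assemble_single_elements(hits, genome)
        assert len(elements) == 2
        assign = group_copies(elements, genome)
        assert len(set(assign.values())) == 2  # 50% alignable -> not copies


class TestAutonomyAndCargo:
    def test_embedded_transposase_detected_both_strands(self):
        rng = np.random.default_rng(7)
        prot = sg.random_protein(rng, 150)
        lib = {"TP": prot}
        thr = autonomy_threshold(lib, seed=1)
        orf = sg.encode_protein(prot[:100], rng)
        fwd = sg.random_seq(rng, 400) + orf + sg.random_seq(rng, 400)
        rev = revcomp(fwd)
        rand = sg.random_seq(rng, 1000)
        assert best_transposase_score(fwd, lib) >= thr
        assert best_transposase_score(rev, lib) >= thr
        assert best_transposase_score(rand, lib) < thr

    def test_cargo_hit_covers_truth_interval(self, world):
        for t in world.truths:
            if t.cargo is None:
                continue
            e = world.truth_match(t)
            assert e.cargo_hits, t.element_id
            spans = [(h.t_start, h.t_end) for h in e.cargo_hits]
            lo = min(x for x, _ in spans)
            hi = max(y for _, y in spans)
            assert abs(lo - t.cargo[0]) <= 5 and abs(hi - t.cargo[1]) <= 5

    def test_cargo_split_by_nested_repeat_two_hits(self):
        rng = np.random.default_rng(8)
        gene = sg.random_seq(rng, 300)
        foreign = sg.random_seq(rng, 400)
        internal = (
            sg.random_seq(rng, 100) + gene[:150] + foreign + gene[150:]
            + sg.random_seq(rng, 100)
        )
        hits = find_cargo(internal, {"G": gene})
        assert len(hits) == 2

    def test_no_cargo_empty(self):
        rng = np.random.default_rng(9)
        assert find_cargo(sg.random_seq(rng, 800), {"G": sg.random_seq(rng, 300)}) == []


class TestSizesAndReports:
    def test_span_arithmetic_1based(self):
        from mulefinder.fastaio import span_length_1based

        assert span_length_1based(29724087, 29725458) == 1372
        assert span_length_1based(12038207, 12039150) == 944

    def test_nested_repeat_excluded_from_size(self, world):
        nested = [t for t in world.truths if t.nested is not None]
        # the small world has no nested implants; construct one directly
        rng = np.random.default_rng(10)
        foreign = sg.random_seq(rng, 400)
        spec = sg.make_element_spec(rng, "single", "F", nested_seq=foreign)
        bg = sg.generate_background(sg.GenomeSpec(30_000, 0.5, 21))
        genome, truths = sg.implant(bg, [spec], seed=4)
        t = truths[0]
        from mulefinder.annotator import ElementRecord

        e = ElementRecord(
            element_id="E1", family="F", start=t.start, end=t.end,
            architecture="single", tirs=[],
        )
        span = t.end - t.start
        assert element_size(e, genome, {}) == span
        assert element_size(e, genome, {"FOREIGN": foreign}) == span - 400

    def test_size_histogram_bins_and_exclusion(self):
        counts, excluded = size_histogram([944, 1372, 1372, 2500])
        assert counts[9] == 1  # [900, 1000)
        assert counts[13] == 2  # [1300, 1400)
        assert excluded == 1
        empty, none_excluded = size_histogram([])
        assert empty.sum() == 0 and none_excluded == 0

    def test_family_report_percentages(self, world):
        df = family_report(world.elements)
        body = df[df.family != "Total"]
        total = df[df.family == "Total"].iloc[0]
        assert total.copies == body.copies.sum()
        assert total.with_tsd == body.with_tsd.sum()
        for _, row in body.iterrows():
            assert row.pct_tsd == round(100.0 * row.with_tsd / row.copies, 1)

    def test_summarize_counts_example(self):
        df = pd.DataFrame(
            {"family": ["A", "B"], "copies": [4017, 8],
             "with_tsd": [2609, 1], "autonomous": [3, 0]}
        )
        out = summarize_family_counts(df)
        assert out.loc[0, "pct_tsd"] == 64.9
        assert out.loc[1, "pct_tsd"] == 12.5
        tot = out[out.family == "Total"].iloc[0]
        assert tot.copies == 4025 and tot.with_tsd == 2610
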