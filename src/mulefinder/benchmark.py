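"""Implant-recovery benchmark: seeded ground-truth genomes, full-chain
annotation, and per-criterion violator checks.

The benchmark implants 30 elements spanning all seven architectures
(copy divergence 5%, arm identity 96%, TSD lengths 9-11, one compliant
10 bp terminal truncation) into a 2 Mb background, runs discovery ->
curation -> scan -> assembly -> copy grouping, and scores recovery
against the exact simulator truth.  Violator genomes carry one element
each breaking exactly one of the five multi-TIR filters; the check
confirms the pipeline excludes it for the right reason.
"""

from __future__ import annotations

import numpy as np

from . import synthgenome as sg
from .alignment import revcomp
from .annotator import (
    assemble_elements,
    autonomy_threshold,
    best_transposase_score,
    group_copies,
    make_cargo_index,
    scan_genome,
)
from .irfinder import find_inverted_repeats
from .tirlib import TirFamily, curate_pair, deduplicate

ARCH_COPIES = {
    "single": 5, "type1": 5, "type2": 5, "type3": 4,
    "type4": 4, "type5": 4, "type6": 3,
}


def benchmark_world(seed: int, genome_length: int = 2_000_000):
    """Simulated genome, truth, and auxiliary libraries for recovery."""
    rng = np.random.default_rng(seed)
    cargo = {"CARGO-1": sg.random_seq(rng, 320)}
    protein = {"TPASE-1": sg.random_protein(rng, 220)}
    specs = []
    for i, (arch, n) in enumerate(ARCH_COPIES.items()):
        trunc = None
        if arch == "single":
            trunc = tuple((10, 0) if c == n - 1 else (0, 0) for c in range(n))
        specs.append(
            sg.make_element_spec(
                rng, arch, f"BM{i + 1:02d}",
                tir_len=150, internal_len=700,
                tir_arm_identity=0.96, tir_spacing=100,
                tsd_len=9 + i % 3, n_copies=n, copy_divergence=0.05,
                cargo_seq=cargo["CARGO-1"] if arch in ("type1", "type5") else None,
                transposase_protein=protein["TPASE-1"] if arch == "type6" else None,
                copy_truncations=trunc,
            )
        )
    # distinct sub-seeds: reusing the spec-generator seed for the
    # background would replay the same random stream and copy the
    # family TIRs into the background verbatim
    bg = sg.generate_background(sg.GenomeSpec(genome_length, 0.42, seed + 1))
    genome, truths = sg.implant(bg, specs, seed=seed + 2)
    return genome, truths, cargo, protein


def _tsd_correct(element, truth) -> bool:
    tsd = element.tsd
    if tsd is None:
        return False
    return (
        tsd.left_end > truth.tsd_left[0]
        and tsd.left_start < truth.tsd_left[1]
        and tsd.right_end > truth.tsd_right[0]
        and tsd.right_start < truth.tsd_right[1]
    )


def run_recovery(seed: int, genome_length: int = 2_000_000) -> dict:
    """Full-chain recovery metrics against simulator truth.

    Returns recovery / architecture / TSD accuracies (percent over the
    implanted copies) and whether the inferred copy-family partition
    equals the truth partition exactly.
    """
    genome, truths, cargo, protein = benchmark_world(seed, genome_length)
    pairs = find_inverted_repeats(genome)
    curated = [
        (r.representative, r.arm_identity, "")
        for p in pairs
        if (r := curate_pair(genome, p)).accepted
    ]
    library = deduplicate(curated)
    hits = scan_genome(genome, library)
    thr = autonomy_threshold(protein, seed=seed)
    assembly = assemble_elements(
        hits, genome,
        cargo_index=make_cargo_index(cargo),
        transposase_check=lambda s: best_transposase_score(s, protein) >= thr,
    )
    elements = assembly.elements
    group_copies(elements, genome)

    matched = {}
    for t in truths:
        for e in elements:
            if abs(e.start - t.start) <= 3 and abs(e.end - t.end) <= 3:
                matched[t.element_id] = e
                break
    n = len(truths)
    recovered = len(matched)
    arch_ok = sum(
        1 for t in truths
        if t.element_id in matched
        and matched[t.element_id].architecture == t.architecture
    )
    tsd_ok = sum(
        1 for t in truths
        if t.element_id in matched and _tsd_correct(matched[t.element_id], t)
    )
    partition_ok = False
    if recovered == n:
        by_truth_family: dict[str, set[str]] = {}
        for t in truths:
            by_truth_family.setdefault(t.family, set()).add(
                matched[t.element_id].copy_family
            )
        inferred = {e.copy_family for e in matched.values()}
        partition_ok = (
            all(len(v) == 1 for v in by_truth_family.values())
            and len(inferred) == len(by_truth_family)
        )
    return {
        "n_implanted": n,
        "n_library_families": len(library),
        "recovery_pct": 100.0 * recovered / n,
        "architecture_accuracy_pct": 100.0 * arch_ok / n,
        "tsd_accuracy_pct": 100.0 * tsd_ok / n,
        "copy_partition_exact": partition_ok,
    }


def _implant_at(bg: str, element: str, pos: int, tsd: str, tsd_right: str | None = None):
    """Manual insertion with explicit TSD copies (for violators)."""
    right = tsd if tsd_right is None else tsd_right
    return bg[:pos] + tsd + element + right + bg[pos:]


def check_violators(seed: int) -> dict[str, bool]:
    """One purpose-built violator per multi-TIR filter.

    Each genome carries a type-2-like element breaking exactly one
    criterion; the check passes when no multi-TIR element is accepted
    there and (where a candidate can form) the reject record names the
    violated criterion.
    """
    rng = np.random.default_rng(seed)
    tir = sg.random_seq(rng, 150)
    inner = sg.mutate(tir, 6, rng)
    library = [TirFamily(family_id="VL1", representative=tir, source_identity=100.0)]
    tsd = sg.random_seq(rng, 9)

    def type2_like(spacing=100, internal_len=700, n_gap=False, inner_len=None):
        ia = inner if inner_len is None else inner[:inner_len]
        internal = sg.random_seq(rng, internal_len)
        if n_gap:
            mid = internal_len // 2
            internal = internal[:mid] + "N" * 50 + internal[mid:]
        sp1, sp2 = sg.random_seq(rng, spacing), sg.random_seq(rng, spacing)
        return tir + sp1 + ia + internal + revcomp(ia) + sp2 + revcomp(tir)

    results: dict[str, bool] = {}

    def run(element, tsd_right=None, left_chop=0):
        bg = sg.random_seq(rng, 40_000)
        elem = element[left_chop:]
        genome = _implant_at(bg, elem, 20_000, tsd, tsd_right)
        hits = scan_genome(genome, library)
        assembly = assemble_elements(hits, genome)
        multi = [e for e in assembly.elements if e.architecture != "single"]
        return multi, assembly.rejects

    # criterion 1: sequencing gap (N run) between the external TIRs
    multi, rejects = run(type2_like(n_gap=True))
    results["span_or_gap"] = not multi and any(
        "span_or_gap" in r.failed for r in rejects
    )
    # criterion 2: extra TIRs of 40 bp never count as TIRs
    multi, rejects = run(type2_like(inner_len=40))
    results["tir_length"] = not multi
    # criterion 3: 25 bp truncation at the left external terminus
    multi, rejects = run(type2_like(), left_chop=25)
    results["truncation"] = not multi and any(
        "truncation" in r.failed for r in rejects
    )
    # criterion 4: tandem partners 700 bp from the external TIRs
    multi, rejects = run(type2_like(spacing=700))
    results["tandem_distance"] = not multi and any(
        "tandem_distance" in r.failed for r in rejects
    )
    # criterion 5: the right TSD copy is destroyed.  The element must be
    # certifiably TSD-free: a chance direct repeat can appear at the
    # boundaries of any random construction, so flanks are redrawn
    # until no window qualifies under the annotator's search.
    from .irfinder import detect_tsd

    broken = "".join(
        {"A": "C", "C": "G", "G": "T", "T": "A"}[b] for b in tsd
    )
    element = type2_like()
    for _ in range(100):
        bg = sg.random_seq(rng, 40_000)
        genome = _implant_at(bg, element, 20_000, tsd, broken)
        lb = 20_000 + len(tsd)
        rb = lb + len(element)
        scan = detect_tsd(
            genome, lb, rb, left_offsets=(-2, 6), right_offsets=(-6, 2)
        )
        if not scan:
            break
    else:  # pragma: no cover - 100 redraws failing is astronomically rare
        raise RuntimeError("could not construct a TSD-free violator")
    hits = scan_genome(genome, library)
    assembly = assemble_elements(hits, genome)
    multi = [e for e in assembly.elements if e.architecture != "single"]
    results["tsd"] = not multi and any(
        "tsd" in r.failed for r in assembly.rejects
    )
    return results
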