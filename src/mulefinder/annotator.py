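"""Genome annotation with a TIR library: element assembly and taxonomy.

Scans a genome with curated TIR family representatives, assembles hits
into elements (one pair of TIRs = one element), classifies atypical
elements carrying extra TIRs into six architectures, groups copies into
families, calls autonomy (transposase similarity) and Pack-MULE cargo,
and computes repeat-masked element sizes and size distributions.

Multi-TIR calls apply five filters: (1) external TIRs within ``max_span``
with no sequencing gap (N run) between them, (2) every counted TIR at
least ``min_tir_len`` long, (3) external-terminus truncation at most
``max_ext_truncation``, (4) tandem partner TIRs closer than
``tandem_window``, and (5) a 9-11 bp TSD with at most 2 mismatches
flanking the external boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import KmerIndex, LocalHit, encode, glocal_identity, local_hits, revcomp
from .irfinder import Tsd, TsdScan, detect_tsd
from .tirlib import TirFamily

#: criterion identifiers used in reject records
CRITERIA = {
    1: "span_or_gap",
    2: "tir_length",
    3: "truncation",
    4: "tandem_distance",
    5: "tsd",
}


@dataclass(frozen=True)
class TirHit:
    """One local match of a family representative on the genome.

    ``q_start``/``q_end`` are representative coordinates (position 0 =
    the TIR's outer terminus); for a hit playing an external role,
    ``q_start`` estimates the truncation at the element edge.
    """

    family: str
    start: int
    end: int
    strand: str
    matches: int
    q_start: int
    q_end: int
    rep_len: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.length


@dataclass
class ElementRecord:
    """An assembled element: external TIR pair plus any extra TIRs."""

    element_id: str
    family: str
    start: int
    end: int
    architecture: str  # single | type1..type6
    tirs: list[tuple[TirHit, str]]  # (hit, role); roles external/internal/solo
    tsd: Tsd | None = None
    tsd_status: str = "absent"
    cargo_hits: list[LocalHit] = field(default_factory=list)
    autonomous: bool | None = None
    copy_family: str | None = None
    size: int | None = None

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def strand(self) -> str:
        return self.tirs[0][0].strand

    def external_hits(self) -> tuple[TirHit, TirHit]:
        ext = [h for h, role in self.tirs if role == "external"]
        return ext[0], ext[-1]

    def internal_interval(self) -> tuple[int, int]:
        """Region strictly between the external arms' inner ends."""
        left, right = self.external_hits()
        return left.end, right.start


@dataclass
class RejectRecord:
    """A multi-TIR candidate that failed one or more of the filters."""

    family: str
    start: int
    end: int
    failed: list[str]


@dataclass
class AssemblyResult:
    elements: list[ElementRecord]
    orphans: list[TirHit]
    rejects: list[RejectRecord]


def scan_genome(
    genome: str,
    library: list[TirFamily],
    min_len: int = 50,
    min_identity: float = 80.0,
    seed_k: int = 10,
) -> list[TirHit]:
    """Locate every library TIR on the genome, both orientations.

    Overlapping same-family reports are merged to the best-scoring hit;
    output is sorted by position then family for determinism.
    """
    if not library:
        warnings.warn("empty TIR library: no hits possible", stacklevel=2)
        return []
    index = KmerIndex(genome, seed_k)
    enc = encode(genome)
    hits: list[TirHit] = []
    for fam in library:
        rep = fam.representative.upper()
        for h in local_hits(
            rep, index, enc,
            min_len=min_len, min_identity=min_identity, seed_k=seed_k,
        ):
            hits.append(
                TirHit(
                    family=fam.family_id,
                    start=h.t_start,
                    end=h.t_end,
                    strand=h.strand,
                    matches=h.matches,
                    q_start=h.q_start,
                    q_end=h.q_end,
                    rep_len=len(rep),
                )
            )
    hits.sort(key=lambda h: (h.start, h.end, h.family, h.strand))
    return hits


def _external_tsd(
    genome: str,
    left: TirHit,
    right: TirHit,
    *,
    tsd_len_range: tuple[int, int] = (9, 11),
    tsd_max_mismatch: int = 2,
    abut_tol: int = 2,
) -> TsdScan:
    """TSD search at the external boundaries of a candidate element.

    The left window may slide outward by up to the left hit's missing
    representative bases (alignment trim) and a few bases inward (the
    extension can overshoot the true terminus over a lucky noise run),
    and symmetrically on the right; a genuinely truncated element keeps
    its TSD at the aligned edge, so offset 0 is always included.
    """
    inward = 6
    return detect_tsd(
        genome,
        left.start,
        right.end,
        len_range=tsd_len_range,
        max_mismatch=tsd_max_mismatch,
        left_offsets=(-left.q_start - abut_tol, inward),
        right_offsets=(-inward, right.q_start + abut_tol),
    )


def _effective_truncation(hit: TirHit, side: str, tsd: Tsd | None) -> int:
    """Representative bases genuinely absent at the element's outer edge.

    Without a TSD the full q_start is assumed missing; with one, bases
    between the TSD and the aligned edge are present in the genome and
    only the remainder counts as truncation.
    """
    if tsd is None:
        return hit.q_start
    if side == "left":
        present = hit.start - tsd.left_end
    else:
        present = tsd.right_start - hit.end
    return max(0, hit.q_start - max(0, present))


def _has_n_gap(genome: str, start: int, end: int, min_run: int = 10) -> bool:
    region = genome[start:end].upper()
    return "N" * min_run in region


def classify_candidate(
    genome: str,
    left: TirHit,
    right: TirHit,
    between: list[TirHit],
    *,
    max_span: int = 20000,
    min_tir_len: int = 50,
    max_ext_truncation: int = 15,
    tandem_window: int = 600,
    tsd_len_range: tuple[int, int] = (9, 11),
    tsd_max_mismatch: int = 2,
    cargo_index=None,
    transposase_check=None,
) -> tuple[ElementRecord | None, list[str]]:
    """Apply the five multi-TIR filters and assign an architecture.

    Returns (record, []) on acceptance or (None, failed_criteria).
    ``cargo_index`` is a callable mapping an internal-region sequence to
    cargo hits; ``transposase_check`` maps it to a bool.
    """
    failed: list[str] = []
    tsd_scan = _external_tsd(
        genome, left, right,
        tsd_len_range=tsd_len_range, tsd_max_mismatch=tsd_max_mismatch,
    )
    tsd = tsd_scan.tsd
    if tsd is None:
        failed.append(CRITERIA[5])
        start, end = left.start, right.end
    else:
        start, end = tsd.left_end, tsd.right_start

    if end - start > max_span or _has_n_gap(genome, left.end, right.start):
        failed.append(CRITERIA[1])
    if any(h.length < min_tir_len for h in (left, right, *between)):
        failed.append(CRITERIA[2])
    if (
        _effective_truncation(left, "left", tsd) > max_ext_truncation
        or _effective_truncation(right, "right", tsd) > max_ext_truncation
    ):
        failed.append(CRITERIA[3])

    # architecture: each extra TIR is attributed to its nearer external
    # arm; the strict < tandem_window distance is criterion 4, checked
    # separately so a too-distant tandem partner is reported as such
    def gaps(h: TirHit) -> tuple[int, int]:
        return h.start - left.end, right.start - h.end

    roles: list[tuple[TirHit, str]] = []
    arch: str | None = None
    cargo: list[LocalHit] = []
    internal_seq = ""

    def rebase(hits_, offset):
        # cargo hits are reported in genome coordinates
        import dataclasses

        return [
            dataclasses.replace(
                h, t_start=h.t_start + offset, t_end=h.t_end + offset
            )
            for h in hits_
        ]

    if len(between) == 2:
        a, b = between
        ga_l, ga_r = gaps(a)
        gb_l, gb_r = gaps(b)
        if ga_l <= ga_r and gb_r <= gb_l and a.strand == left.strand and b.strand == right.strand:
            # tandem TIRs on both ends; cargo decides type1 vs type2
            internal_seq = genome[a.end : b.start]
            roles = [(left, "external"), (a, "internal"),
                     (b, "internal"), (right, "external")]
            if ga_l >= tandem_window or gb_r >= tandem_window:
                failed.append(CRITERIA[4])
            cargo = rebase(cargo_index(internal_seq), a.end) if cargo_index else []
            arch = "type1" if cargo else "type2"
        else:
            failed.append("architecture")
    elif len(between) == 1:
        solo = between[0]
        g_l, g_r = gaps(solo)
        if min(g_l, g_r) < tandem_window:
            # solo TIR in tandem with one external arm (type 3)
            adjacent_strand = left.strand if g_l <= g_r else right.strand
            internal_seq = (
                genome[solo.end : right.start]
                if g_l <= g_r
                else genome[left.end : solo.start]
            )
            if solo.strand != adjacent_strand:
                failed.append("architecture")
            else:
                roles = [(left, "external"), (solo, "solo"), (right, "external")]
                off = solo.end if g_l <= g_r else left.end
                cargo = rebase(cargo_index(internal_seq), off) if cargo_index else []
                arch = "type3"
        else:
            # interior solo TIR: cargo -> type5, transposase -> type6
            internal_seq = genome[left.end : right.start]
            roles = [(left, "external"), (solo, "solo"), (right, "external")]
            cargo = rebase(cargo_index(internal_seq), left.end) if cargo_index else []
            if cargo:
                arch = "type5"
            elif transposase_check and transposase_check(internal_seq):
                arch = "type6"
            else:
                arch = "type4"
    else:
        failed.append("architecture")

    if failed:
        return None, sorted(set(failed))

    rec = ElementRecord(
        element_id="",
        family=left.family,
        start=start,
        end=end,
        architecture=arch,
        tirs=roles,
        tsd=tsd,
        tsd_status=tsd_scan.status,
        cargo_hits=list(cargo),
    )
    return rec, []


def assemble_elements(
    hits: list[TirHit],
    genome: str,
    *,
    max_span: int = 20000,
    min_tir_len: int = 50,
    max_ext_truncation: int = 15,
    tandem_window: int = 600,
    tsd_len_range: tuple[int, int] = (9, 11),
    tsd_max_mismatch: int = 2,
    cargo_index=None,
    transposase_check=None,
) -> AssemblyResult:
    """Assemble scan hits into single and multi-TIR elements.

    Per family, each leftmost unused hit is paired with the farthest
    opposite-orientation hit (within ``max_span``) that yields a valid
    element: with extra hits in between the five multi-TIR filters must
    all pass; with none, the pair forms a single-TIR-pair element.
    External partners must be of comparable length (the shorter at
    least half the longer), so a marginal ~50 bp background hit cannot
    pair with a genuine full-length arm kilobases away.  Failed
    multi-TIR candidates are recorded as rejects; unpairable hits
    become orphans.
    """
    elements: list[ElementRecord] = []
    orphans: list[TirHit] = []
    rejects: list[RejectRecord] = []
    opposite = {"+": "-", "-": "+"}

    by_family: dict[str, list[TirHit]] = {}
    for h in hits:
        by_family.setdefault(h.family, []).append(h)

    for family in sorted(by_family):
        fam_hits = sorted(by_family[family], key=lambda h: (h.start, h.end))
        used = [False] * len(fam_hits)
        for i, left in enumerate(fam_hits):
            if used[i]:
                continue
            partners = [
                j
                for j in range(i + 1, len(fam_hits))
                if not used[j]
                and fam_hits[j].strand == opposite[left.strand]
                and fam_hits[j].end - left.start <= max_span
                and min(fam_hits[j].length, left.length)
                >= 0.5 * max(fam_hits[j].length, left.length)
            ]
            chosen = None
            candidate_rejects: list[RejectRecord] = []
            stopped: tuple | None = None
            for j in sorted(partners, key=lambda j: fam_hits[j].end, reverse=True):
                right = fam_hits[j]
                between_idx = [k for k in range(i + 1, j) if not used[k]]
                between = [fam_hits[k] for k in between_idx]
                if not between:
                    tsd_scan = _external_tsd(
                        genome, left, right,
                        tsd_len_range=tsd_len_range,
                        tsd_max_mismatch=tsd_max_mismatch,
                    )
                    tsd = tsd_scan.tsd
                    start, end = (
                        (tsd.left_end, tsd.right_start) if tsd else (left.start, right.end)
                    )
                    rec = ElementRecord(
                        element_id="",
                        family=family,
                        start=start,
                        end=end,
                        architecture="single",
                        tirs=[(left, "external"), (right, "external")],
                        tsd=tsd,
                        tsd_status=tsd_scan.status,
                    )
                    chosen = (j, [i, j], rec)
                    break
                rec, failed = classify_candidate(
                    genome, left, right, between,
                    max_span=max_span,
                    min_tir_len=min_tir_len,
                    max_ext_truncation=max_ext_truncation,
                    tandem_window=tandem_window,
                    tsd_len_range=tsd_len_range,
                    tsd_max_mismatch=tsd_max_mismatch,
                    cargo_index=cargo_index,
                    transposase_check=transposase_check,
                )
                if rec is not None:
                    chosen = (j, [i, j, *between_idx], rec)
                    break
                candidate_rejects.append(
                    RejectRecord(family, left.start, right.end, failed)
                )
                if "architecture" not in failed:
                    # a structurally valid element failed the filters:
                    # stop retrying inner pairings (they would only form
                    # spurious smaller elements), demote the external
                    # pair to a single-TIR-pair element, consume extras
                    stopped = (j, between_idx)
                    break
            if stopped is not None:
                j, between_idx = stopped
                right = fam_hits[j]
                rejects.append(candidate_rejects[-1])
                tsd_scan = _external_tsd(
                    genome, left, right,
                    tsd_len_range=tsd_len_range,
                    tsd_max_mismatch=tsd_max_mismatch,
                )
                tsd = tsd_scan.tsd
                start, end = (
                    (tsd.left_end, tsd.right_start) if tsd else (left.start, right.end)
                )
                elements.append(
                    ElementRecord(
                        element_id="",
                        family=family,
                        start=start,
                        end=end,
                        architecture="single",
                        tirs=[(left, "external"), (right, "external")],
                        tsd=tsd,
                        tsd_status=tsd_scan.status,
                    )
                )
                for k in (i, j, *between_idx):
                    used[k] = True
                for k in between_idx:
                    orphans.append(fam_hits[k])
            elif chosen is not None:
                _, consumed, rec = chosen
                for k in consumed:
                    used[k] = True
                elements.append(rec)
            else:
                used[i] = True
                orphans.append(left)
                if candidate_rejects:
                    rejects.append(candidate_rejects[0])
        for k, h in enumerate(fam_hits):
            if not used[k]:
                orphans.append(h)
                used[k] = True

    elements.sort(key=lambda e: (e.start, e.end, e.family))
    for n, e in enumerate(elements, 1):
        e.element_id = f"EL{n:04d}"
    orphans.sort(key=lambda h: (h.start, h.family))
    return AssemblyResult(elements, orphans, rejects)


def assemble_single_elements(
    hits: list[TirHit],
    genome: str,
    *,
    max_span: int = 20000,
    tsd_len_range: tuple[int, int] = (9, 11),
    tsd_max_mismatch: int = 2,
) -> tuple[list[ElementRecord], list[TirHit]]:
    """Pair nearest opposite-orientation same-family hits into elements.

    One pair of TIRs is one element; a TSD is attached when found.
    Hits with no admissible partner are returned as orphans.
    """
    elements: list[ElementRecord] = []
    orphans: list[TirHit] = []
    opposite = {"+": "-", "-": "+"}
    by_family: dict[str, list[TirHit]] = {}
    for h in hits:
        by_family.setdefault(h.family, []).append(h)
    for family in sorted(by_family):
        fam_hits = sorted(by_family[family], key=lambda h: (h.start, h.end))
        used = [False] * len(fam_hits)
        for i, left in enumerate(fam_hits):
            if used[i]:
                continue
            partner = None
            for j in range(i + 1, len(fam_hits)):
                if used[j]:
                    continue
                right = fam_hits[j]
                if (
                    right.strand == opposite[left.strand]
                    and right.end - left.start <= max_span
                    and min(right.length, left.length)
                    >= 0.5 * max(right.length, left.length)
                ):
                    partner = j
                    break
            if partner is None:
                used[i] = True
                orphans.append(left)
                continue
            right = fam_hits[partner]
            used[i] = used[partner] = True
            tsd_scan = _external_tsd(
                genome, left, right,
                tsd_len_range=tsd_len_range, tsd_max_mismatch=tsd_max_mismatch,
            )
            tsd = tsd_scan.tsd
            start, end = (tsd.left_end, tsd.right_start) if tsd else (left.start, right.end)
            elements.append(
                ElementRecord(
                    element_id="",
                    family=family,
                    start=start,
                    end=end,
                    architecture="single",
                    tirs=[(left, "external"), (right, "external")],
                    tsd=tsd,
                    tsd_status=tsd_scan.status,
                )
            )
    elements.sort(key=lambda e: (e.start, e.end, e.family))
    for n, e in enumerate(elements, 1):
        e.element_id = f"EL{n:04d}"
    return elements, orphans


def make_cargo_index(
    cargo_seqs: dict[str, str],
    *,
    min_len: int = 50,
    min_identity: float = 80.0,
    seed_k: int = 10,
):
    """Callable returning cargo hits for an internal-region sequence.

    Hit target coordinates refer to the internal region (so they can be
    rebased into genome space); query coordinates index the cargo
    sequence.
    """
    library = {name: s.upper() for name, s in sorted(cargo_seqs.items())}

    def query(internal: str) -> list[LocalHit]:
        if len(internal) < min_len:
            return []
        idx = KmerIndex(internal, seed_k)
        enc = encode(internal)
        out = []
        for name, seq in library.items():
            out.extend(
                local_hits(
                    seq, idx, enc,
                    min_len=min_len, min_identity=min_identity, seed_k=seed_k,
                )
            )
        out.sort(key=lambda h: (h.t_start, h.t_end))
        return out

    return query


def find_cargo(
    internal: str,
    cargo_seqs: dict[str, str],
    *,
    min_len: int = 50,
    min_identity: float = 80.0,
) -> list[LocalHit]:
    """Local matches of an internal region against a cargo library.

    Hits above ``min_identity`` / ``min_len`` mark the element as a
    Pack-MULE; target coordinates refer to the internal region, query
    coordinates to the matched cargo sequence.
    """
    return make_cargo_index(
        cargo_seqs, min_len=min_len, min_identity=min_identity
    )(internal)


def six_frame_segments(seq: str, min_aa: int = 20) -> list[str]:
    """Stop-free translated segments of all six reading frames."""
    from Bio.Seq import Seq

    out = []
    for strand_seq in (seq, revcomp(seq)):
        for frame in range(3):
            sub = strand_seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            aa = str(Seq(sub).translate())
            out.extend(s for s in aa.split("*") if len(s) >= min_aa)
    return out


def _protein_sw_score(a: str, b: str) -> int:
    import biotite.sequence as bseq
    import biotite.sequence.align as balign

    matrix = balign.SubstitutionMatrix.std_protein_matrix()
    try:
        pa = bseq.ProteinSequence(a)
        pb = bseq.ProteinSequence(b)
    except Exception:
        return 0
    alns = balign.align_optimal(
        pa, pb, matrix, local=True, gap_penalty=(-11, -1), max_number=1
    )
    return alns[0].score if alns else 0


def best_transposase_score(internal: str, proteins: dict[str, str]) -> int:
    """Best Smith-Waterman score of any six-frame segment vs the library."""
    best = 0
    for seg in six_frame_segments(internal):
        for prot in proteins.values():
            best = max(best, _protein_sw_score(seg, prot))
    return best


def autonomy_threshold(
    proteins: dict[str, str],
    *,
    length: int = 2000,
    n_shuffles: int = 25,
    seed: int = 0,
    margin: float = 1.5,
) -> int:
    """Score threshold calibrated on a shuffle null.

    Scores ``n_shuffles`` random sequences of ``length`` bases against
    the library and returns ``margin`` times the null maximum, so that
    random internal regions are called non-autonomous while a
    100-residue identical transposase match scores far above it.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    null = [
        best_transposase_score("".join(rng.choice(bases, size=length)), proteins)
        for _ in range(n_shuffles)
    ]
    return int(np.ceil(max(null) * margin))


def classify_autonomous(
    internal: str,
    proteins: dict[str, str] | None,
    threshold: int | None = None,
    **calib_kwargs,
) -> bool | None:
    """Transposase-similarity autonomy flag for one internal region.

    Returns None (undefined, not False) when no protein library is
    supplied.  ``threshold`` defaults to a shuffle-calibrated value.
    """
    if not proteins:
        return None
    if threshold is None:
        threshold = autonomy_threshold(proteins, **calib_kwargs)
    return best_transposase_score(internal, proteins) >= threshold


def group_copies(
    elements: list[ElementRecord],
    genome: str,
    *,
    min_internal_fraction: float = 0.70,
    min_identity: float = 80.0,
    min_tir_align: int = 100,
    seed_k: int = 10,
) -> dict[str, str]:
    """Partition elements into copy families.

    Two elements are copies when their TIRs align (>= ``min_tir_align``
    bases, or the full TIR if shorter, at >= ``min_identity``) and more
    than ``min_internal_fraction`` of the shorter internal region is
    covered by local alignments to the other's.  The transitive closure
    of the copy relation defines families; labels are assigned CF01,
    CF02, ... by leftmost member.  Elements without an internal region
    are compared on TIRs alone.
    """

    def oriented_internal(e: ElementRecord) -> str:
        s, t = e.internal_interval()
        seq = genome[s:t].upper()
        return seq if e.strand == "+" else revcomp(seq)

    def oriented_tir(e: ElementRecord) -> str:
        h = e.external_hits()[0]
        seq = genome[h.start : h.end].upper()
        return seq if h.strand == "+" else revcomp(seq)

    internals = [oriented_internal(e) for e in elements]
    tirs = [oriented_tir(e) for e in elements]
    n = len(elements)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = tirs[i], tirs[j]
            short, long_ = (a, b) if len(a) <= len(b) else (b, a)
            if len(short) < seed_k:
                continue
            if glocal_identity(short, long_) < min_identity:
                continue
            ia, ib = internals[i], internals[j]
            if min(len(ia), len(ib)) < 2 * seed_k:
                union(i, j)  # back-to-back TIRs: TIR comparison only
                continue
            short_i, long_i = (ia, ib) if len(ia) <= len(ib) else (ib, ia)
            idx = KmerIndex(long_i, seed_k)
            enc = encode(long_i)
            hits = local_hits(
                short_i, idx, enc,
                min_len=min(50, len(short_i)),
                min_identity=min_identity,
                seed_k=seed_k,
                both_strands=False,
            )
            covered = np.zeros(len(short_i), dtype=bool)
            for h in hits:
                covered[h.q_start : h.q_end] = True
            if covered.mean() > min_internal_fraction:
                union(i, j)

    roots: dict[int, list[int]] = {}
    for i in range(n):
        roots.setdefault(find(i), []).append(i)
    assignment: dict[str, str] = {}
    for k, (_, members) in enumerate(
        sorted(roots.items(), key=lambda kv: min(kv[1])), start=1
    ):
        label = f"CF{k:02d}"
        for i in members:
            elements[i].copy_family = label
            assignment[elements[i].element_id] = label
    return assignment


def element_size(
    element: ElementRecord,
    genome: str,
    repeat_library: dict[str, str] | None,
    *,
    min_len: int = 50,
    min_identity: float = 80.0,
    seed_k: int = 10,
) -> int:
    """Element size excluding nested foreign-repeat insertions.

    The span length minus bases covered by repeat-library hits inside
    the element; the repeat library must not contain MULE TIRs.  With
    no library the size equals the span length.
    """
    span = element.span
    if not repeat_library:
        element.size = span
        return span
    seq = genome[element.start : element.end].upper()
    covered = np.zeros(span, dtype=bool)
    idx = KmerIndex(seq, seed_k)
    enc = encode(seq)
    for name in sorted(repeat_library):
        for h in local_hits(
            repeat_library[name].upper(), idx, enc,
            min_len=min_len, min_identity=min_identity, seed_k=seed_k,
        ):
            covered[h.t_start : h.t_end] = True
    size = int(span - covered.sum())
    element.size = size
    return size


def size_histogram(
    sizes: list[int], bin_width: int = 100, max_size: int = 2000
) -> tuple[np.ndarray, int]:
    """Counts per half-open size bin; sizes >= max_size are excluded.

    Returns (counts over [0,bin), [bin,2*bin), ..., n_excluded).
    """
    n_bins = max_size // bin_width
    counts = np.zeros(n_bins, dtype=int)
    excluded = 0
    for s in sizes:
        if s >= max_size:
            excluded += 1
        else:
            counts[s // bin_width] += 1
    return counts, excluded


def summarize_family_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Add TSD / autonomy percentages and a Total row to a census table.

    Expects columns family, copies, with_tsd, autonomous; percentages
    are rounded to 1 decimal, and the Total row is recomputed from the
    column sums.
    """
    df = counts.copy()
    df["pct_tsd"] = (100.0 * df["with_tsd"] / df["copies"]).round(1)
    df["pct_autonomous"] = (100.0 * df["autonomous"] / df["copies"]).round(1)
    total = pd.DataFrame(
        {
            "family": ["Total"],
            "copies": [df["copies"].sum()],
            "with_tsd": [df["with_tsd"].sum()],
            "autonomous": [df["autonomous"].sum()],
        }
    )
    total["pct_tsd"] = (100.0 * total["with_tsd"] / total["copies"]).round(1)
    total["pct_autonomous"] = (
        100.0 * total["autonomous"] / total["copies"]
    ).round(1)
    return pd.concat([df, total], ignore_index=True)


def family_report(elements: list[ElementRecord]) -> pd.DataFrame:
    """Per-TIR-family census: copy number, TSD and autonomy fractions.

    One pair of TIRs counts as one element.  Percentages are rounded to
    one decimal; a Total row sums the counts.
    """
    rows = []
    for family in sorted({e.family for e in elements}):
        fam = [e for e in elements if e.family == family]
        rows.append(
            {
                "family": family,
                "copies": len(fam),
                "with_tsd": sum(1 for e in fam if e.tsd is not None),
                "autonomous": sum(
                    1 for e in fam if e.autonomous is not None and bool(e.autonomous)
                ),
            }
        )
    counts = pd.DataFrame(
        rows, columns=["family", "copies", "with_tsd", "autonomous"]
    )
    if counts.empty:
        return counts
    return summarize_family_counts(counts)


def classify_multi_tir(
    hits: list[TirHit],
    genome: str,
    **kwargs,
) -> tuple[list[ElementRecord], list[RejectRecord]]:
    """Multi-TIR elements among scan hits (types 1-6), plus rejects."""
    result = assemble_elements(hits, genome, **kwargs)
    multi = [e for e in result.elements if e.architecture != "single"]
    return multi, result.rejects
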