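"""Curation of candidate TIR pairs into a nonredundant family library.

A discovered inverted-repeat pair enters the library only if it looks
like a genuine mobile-element boundary: high arm-vs-arm identity over at
least 100 bp, intact termini, and a 9-11 bp target-site duplication
immediately flanking the arms.  Accepted representatives are then
clustered: two TIR sequences sharing >=80% identity over >=80% of the
shorter one's length are redundant, and the representative from the
element with the highest arm identity is retained per family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import alignment
from .alignment import KmerIndex, encode, local_hits, percent_identity, revcomp
from .irfinder import TirPair, Tsd, TsdScan, detect_tsd


@dataclass
class CurationResult:
    """Accept/reject verdict for one candidate pair."""

    accepted: bool
    reasons: list[str]  # empty when accepted
    representative: str | None = None  # left arm, extended to the TSD edge
    arm_identity: float | None = None
    tsd: Tsd | None = None
    left: tuple[int, int] | None = None
    right: tuple[int, int] | None = None


@dataclass
class TirFamily:
    """One nonredundant TIR family of the library."""

    family_id: str
    representative: str
    source_identity: float
    source_id: str = ""
    member_count: int = 1
    members: list[str] = field(default_factory=list)


def curate_pair(
    seq: str,
    pair: TirPair,
    tsd_scan: TsdScan | None = None,
    *,
    min_len: int = 100,
    min_identity: float = 80.0,
    intact_tol: int = 8,
    tsd_max_mismatch: int = 1,
    truncation_probe: int = 17,
) -> CurationResult:
    """Apply the library-entry criteria to one inverted-repeat pair.

    Accepts iff the arms share >= ``min_identity`` percent identity over
    >= ``min_len`` aligned columns, a near-perfect TSD (at most
    ``tsd_max_mismatch`` substitutions -- curation is the strict,
    hand-verified stage) flanks the arms within ``intact_tol`` bases of
    each detected terminus, and re-scoring after snapping the arms to
    the TSD edges stays above threshold.  The tolerance absorbs the few
    bases by which a maximal-scoring extension can under- or overshoot
    a diverged arm's true terminus; the TSD then fixes the boundary
    exactly.  When no TSD qualifies but one is found within
    ``truncation_probe`` bases, the reject reason is ``truncated_end``
    rather than ``no_tsd``.
    """
    reasons: list[str] = []
    if tsd_scan is None:
        tsd_scan = detect_tsd(
            seq, pair.left_start, pair.right_end,
            abut_tol=intact_tol, max_mismatch=tsd_max_mismatch,
        )
    if tsd_scan.status == "insufficient_flank":
        reasons.append("insufficient_flank")
    elif tsd_scan.status == "absent":
        wide = detect_tsd(
            seq, pair.left_start, pair.right_end, abut_tol=truncation_probe
        )
        reasons.append("truncated_end" if wide else "no_tsd")

    tsd = tsd_scan.tsd
    if tsd is not None and _snap_inconsistent(seq, pair, tsd):
        # the TSD would shave off columns that still align arm-to-arm:
        # a chance direct repeat inward of the true terminus, not the
        # real insertion-site duplication
        reasons.append("boundary_inconsistent")
        tsd = None
    if tsd is not None:
        left = (tsd.left_end, pair.left_end)
        right = (pair.right_start, tsd.right_start)
    else:
        left = (pair.left_start, pair.left_end)
        right = (pair.right_start, pair.right_end)
    left_seq = seq[left[0] : left[1]].upper()
    right_seq = seq[right[0] : right[1]].upper()
    identity = percent_identity(left_seq, revcomp(right_seq))
    aligned = max(len(left_seq), len(right_seq))
    if aligned < min_len:
        reasons.append("short_alignment")
    if identity < min_identity:
        reasons.append("low_identity")

    if reasons:
        return CurationResult(False, reasons, tsd=tsd, left=left, right=right)
    return CurationResult(
        True,
        [],
        representative=left_seq,
        arm_identity=identity,
        tsd=tsd,
        left=left,
        right=right,
    )


def _snap_inconsistent(
    seq: str,
    pair: TirPair,
    tsd: Tsd,
    min_shift: int = 3,
    max_match: float = 0.6,
) -> bool:
    """True when snapping arms to the TSD drops well-matching columns.

    Columns between the TSD edge and the detected arm end lie on the
    pair's anti-diagonal; if a shrink of >= ``min_shift`` bases removes
    columns that still match their inverted partners at >=
    ``max_match``, the window looks like part of the arm and the TSD is
    a chance repeat inward of the true terminus.
    """
    comp = dict(zip("ACGT", "TGCA"))
    D = pair.left_start + pair.right_end - 1

    def diag_match_frac(xs: range) -> float:
        n = hit = 0
        for x in xs:
            y = D - x
            if 0 <= x < len(seq) and 0 <= y < len(seq):
                a, b = seq[x].upper(), seq[y].upper()
                n += 1
                hit += a in comp and comp[a] == b
        return hit / n if n else 0.0

    shrink_l = tsd.left_end - pair.left_start
    if shrink_l >= min_shift:
        if diag_match_frac(range(pair.left_start, tsd.left_end)) >= max_match:
            return True
    shrink_r = pair.right_end - tsd.right_start
    if shrink_r >= min_shift:
        if diag_match_frac(range(D - pair.right_end + 1, D - tsd.right_start + 1)) >= max_match:
            return True
    return False


def is_redundant(
    a: str,
    b: str,
    *,
    min_identity: float = 80.0,
    min_cover: float = 0.80,
    seed_k: int = 10,
) -> bool:
    """True when two TIR sequences are the same family.

    Checks both orientations for a local similarity of >=
    ``min_identity`` percent covering >= ``min_cover`` of the shorter
    sequence's length.
    """
    if len(a) < len(b):
        a, b = b, a
    need = max(seed_k, math.ceil(min_cover * len(b)))
    idx = KmerIndex(a, min(seed_k, len(b)))
    enc = encode(a)
    hits = local_hits(
        b, idx, enc, min_len=need, min_identity=min_identity, seed_k=min(seed_k, len(b))
    )
    return bool(hits)


def deduplicate(
    candidates: list[tuple[str, float] | tuple[str, float, str]],
    *,
    min_identity: float = 80.0,
    min_cover: float = 0.80,
    prefix: str = "SYN-MULE",
) -> list[TirFamily]:
    """Greedy redundancy clustering of curated TIR candidates.

    Candidates are ordered by source arm identity descending (ties:
    longer sequence, then lexicographically smaller), so each family's
    representative is the TIR from the element with the highest arm
    identity.  A candidate joins the first existing family it is
    redundant with; otherwise it founds a new one.
    """
    norm = []
    for c in candidates:
        seq, ident = c[0].upper(), float(c[1])
        src = c[2] if len(c) > 2 else ""
        norm.append((seq, ident, src))
    norm.sort(key=lambda t: (-t[1], -len(t[0]), t[0]))

    families: list[TirFamily] = []
    for seq, ident, src in norm:
        for fam in families:
            if is_redundant(
                fam.representative, seq,
                min_identity=min_identity, min_cover=min_cover,
            ):
                fam.member_count += 1
                fam.members.append(src or seq)
                break
        else:
            fam = TirFamily(
                family_id=f"{prefix}{len(families) + 1:02d}",
                representative=seq,
                source_identity=ident,
                source_id=src,
            )
            fam.members.append(src or seq)
            families.append(fam)
    return families


def check_nonredundant(families: list[TirFamily], **kwargs) -> bool:
    """Post-hoc invariant: no two representatives are redundant."""
    for i, a in enumerate(families):
        for b in families[i + 1 :]:
            if is_redundant(a.representative, b.representative, **kwargs):
                return False
    return True
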