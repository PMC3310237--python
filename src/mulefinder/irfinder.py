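"""De novo discovery of long inverted repeats and flanking TSDs.

An inverted repeat is a pair of arms on the same sequence where the
right arm is (approximately) the reverse complement of the left arm.
Under a substitution-only model every such pair lies on one
anti-diagonal of the sequence-versus-reverse-complement comparison:
position x of the left arm pairs with position D - x of the right arm
for a constant D.  Discovery seeds exact ``seed_k``-mer / reverse
complement matches, evaluates each seeded anti-diagonal exhaustively,
and reports maximal windows above the identity and length thresholds.
Any true pair sharing at least one exact seed k-mer is therefore found.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .alignment import best_segments, encode, kmer_codes_of


@dataclass(frozen=True)
class TirPair:
    """Two inverted arms of a candidate TIR (0-based half-open)."""

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    matches: int

    def __post_init__(self):
        if not self.left_end <= self.right_start:
            raise ValueError("left arm must strictly precede right arm")

    @property
    def length(self) -> int:
        return self.left_end - self.left_start

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.length

    @property
    def span(self) -> int:
        return self.right_end - self.left_start


@dataclass(frozen=True)
class Tsd:
    """A flanking target-site duplication (direct repeat, no indels)."""

    sequence: str
    mismatches: int
    left_start: int
    left_end: int
    right_start: int
    right_end: int

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TsdScan:
    """Outcome of a TSD search.

    ``status`` distinguishes a completed search with no hit ('absent')
    from a search that could not run because the flanks were shorter
    than the largest window ('insufficient_flank').
    """

    status: str  # found | absent | insufficient_flank
    tsd: Tsd | None = None

    def __bool__(self) -> bool:
        return self.tsd is not None


def _n_split_runs(seq: str, min_len: int) -> list[tuple[int, int]]:
    return [
        (m.start(), m.end())
        for m in re.finditer(r"[Nn]+", seq)
        if m.end() - m.start() >= min_len
    ]


def find_inverted_repeats(
    seq: str,
    min_len: int = 100,
    min_identity: float = 80.0,
    max_span: int = 20000,
    seed_k: int = 12,
) -> list[TirPair]:
    """All maximal inverted-repeat arm pairs above the thresholds.

    Guaranteed to report every pair whose arms share at least one exact
    ``seed_k``-mer / reverse-complement match, with identity >=
    ``min_identity`` over >= ``min_len`` and span <= ``max_span``.
    Overlapping reports are merged to the best-scoring extension; pairs
    crossing an N run of length >= min_len are suppressed (such runs
    split the search space).  Result sorted by position.
    """
    if min_len < seed_k:
        raise ValueError("min_len must be >= seed_k")
    n = len(seq)
    if n < 2 * min_len:
        return []
    enc = encode(seq)
    rc = seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]

    codes_f, valid_f = kmer_codes_of(seq, seed_k)
    codes_r, valid_r = kmer_codes_of(rc, seed_k)
    pos_f = np.nonzero(valid_f)[0]
    pos_r = np.nonzero(valid_r)[0]
    if pos_f.size == 0 or pos_r.size == 0:
        return []
    cf = codes_f[pos_f]
    order = np.argsort(cf, kind="stable")
    cf_sorted = cf[order]
    pf_sorted = pos_f[order]
    cr = codes_r[pos_r]
    lo = np.searchsorted(cf_sorted, cr, side="left")
    hi = np.searchsorted(cf_sorted, cr, side="right")

    diagonals: set[int] = set()
    for idx in np.nonzero(hi > lo)[0]:
        pr = int(pos_r[idx])
        p2 = n - seed_k - pr  # position of the rc k-mer in seq coordinates
        for p1 in pf_sorted[lo[idx] : hi[idx]]:
            p1 = int(p1)
            if p1 >= p2:
                continue
            if p2 + seed_k - p1 > max_span:
                continue
            diagonals.add(p1 + p2 + seed_k - 1)

    pairs: list[TirPair] = []
    for D in sorted(diagonals):
        x_max = min((D - 1) // 2, n - 1)
        x_min = max(0, D - n + 1, (D + 1 - max_span + 1) // 2)
        if x_max - x_min + 1 < min_len:
            continue
        xs = np.arange(x_min, x_max + 1)
        a = enc[xs]
        b = enc[D - xs]
        match = (a + b == 3) & (a < 4) & (b < 4)
        for s, e, nm in best_segments(match, min_len, min_identity / 100.0, 2.0):
            ls, le = x_min + s, x_min + e
            rs, re_ = D - (le - 1), D - ls + 1
            if re_ - ls > max_span:
                continue
            pairs.append(TirPair(ls, le, rs, re_, int(nm)))

    splits = _n_split_runs(seq, min_len)
    if splits:
        pairs = [
            p
            for p in pairs
            if not any(rs < p.right_end and re_ > p.left_start for rs, re_ in splits)
        ]

    # merge overlapping reports (same repeat found on nearby diagonals)
    kept: list[TirPair] = []
    for p in sorted(pairs, key=lambda p: (-p.matches, -p.length, p.left_start)):
        dup = False
        for q in kept:
            lo_ = min(p.left_end, q.left_end) - max(p.left_start, q.left_start)
            ro_ = min(p.right_end, q.right_end) - max(p.right_start, q.right_start)
            if (
                lo_ > 0.5 * min(p.length, q.length)
                and ro_ > 0.5 * min(p.length, q.length)
            ):
                dup = True
                break
        if not dup:
            kept.append(p)
    kept.sort(key=lambda p: (p.left_start, p.right_start))
    return kept


def detect_tsd(
    seq: str,
    left_boundary: int,
    right_boundary: int,
    len_range: tuple[int, int] = (9, 11),
    max_mismatch: int = 2,
    abut_tol: int = 2,
    left_offsets: tuple[int, int] | None = None,
    right_offsets: tuple[int, int] | None = None,
) -> TsdScan:
    """Search for a direct repeat flanking an element.

    Scans windows of each length in ``len_range`` whose inner edge lies
    within ``abut_tol`` bases of the stated element boundary (left
    window ends at the left boundary, right window starts at the right
    boundary), allowing up to ``max_mismatch`` substitutions and no
    indels.  ``left_offsets`` / ``right_offsets`` override the
    symmetric tolerance with an explicit inclusive offset range, e.g.
    to widen the search inward over a suspected terminal truncation.
    The best hit under (fewest mismatches, most exact abutment,
    longest) ordering is returned: a clean direct repeat abutting the
    boundaries always beats a longer window that needs mismatches or
    an offset, while among equally clean candidates the longest wins.
    """
    lmin, lmax = len_range
    if not 0 <= left_boundary <= right_boundary <= len(seq):
        raise ValueError("boundaries out of range")
    if left_offsets is None:
        left_offsets = (-abut_tol, abut_tol)
    if right_offsets is None:
        right_offsets = (-abut_tol, abut_tol)
    if left_boundary < lmax or len(seq) - right_boundary < lmax:
        return TsdScan("insufficient_flank")

    best: tuple | None = None
    for length in range(lmax, lmin - 1, -1):
        for off_l in range(left_offsets[0], left_offsets[1] + 1):
            le = left_boundary + off_l
            ls = le - length
            if ls < 0 or le > len(seq):
                continue
            left = seq[ls:le].upper()
            for off_r in range(right_offsets[0], right_offsets[1] + 1):
                rs = right_boundary + off_r
                re_ = rs + length
                if rs < 0 or re_ > len(seq):
                    continue
                right = seq[rs:re_].upper()
                mism = sum(1 for x, y in zip(left, right) if x != y or x == "N")
                if mism > max_mismatch:
                    continue
                key = (mism, abs(off_l) + abs(off_r), -length, abs(off_l), off_l, off_r)
                if best is None or key < best[0]:
                    best = (key, Tsd(left, mism, ls, le, rs, re_))
    if best is None:
        return TsdScan("absent")
    return TsdScan("found", best[1])
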