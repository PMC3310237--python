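"""Shared sequence-alignment primitives.

Global percent identity is delegated to edlib (Needleman-Wunsch with an
extended CIGAR); local similarity search is an ungapped seed-and-extend
matcher built on a 2-bit k-mer index.  The ungapped model matches the
substitution-only divergence model used throughout the pipeline; an
exhaustive per-diagonal oracle in the test suite bounds its sensitivity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# A, C, G, T -> 0..3; anything else (N) -> 4 (never matches a k-mer code)
_ENCODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def percent_identity(a: str, b: str) -> float:
    """Global-alignment percent identity of two sequences.

    Identity is matches / alignment columns x 100, where insertion and
    deletion columns count as mismatches.  Symmetric in its arguments:
    the pair is canonicalised before aligning, since the aligner's
    choice among co-optimal alignments depends on argument order.
    """
    if not a or not b:
        raise ValueError("percent_identity requires nonempty sequences")
    a, b = a.upper(), b.upper()
    if (len(b), b) < (len(a), a):
        a, b = b, a
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    columns = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    return 100.0 * matches / columns


def glocal_identity(query: str, target: str) -> float:
    """Identity of the best alignment of the whole query inside target."""
    if not query or not target:
        raise ValueError("glocal_identity requires nonempty sequences")
    res = edlib.align(query.upper(), target.upper(), mode="HW", task="path")
    matches = 0
    columns = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    return 100.0 * matches / columns


class KmerIndex:
    """Sorted-array index of all k-mers of a sequence.

    k-mers overlapping non-ACGT characters are excluded, so N runs break
    the search space naturally.
    """

    def __init__(self, seq: str, k: int):
        if k < 1 or k > 31:
            raise ValueError("k must be in [1, 31]")
        self.k = k
        self.n = len(seq)
        codes, valid = _kmer_codes(encode(seq), k)
        pos = np.nonzero(valid)[0]
        codes = codes[pos]
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = pos[order]

    def lookup(self, code: int) -> np.ndarray:
        """Positions of a k-mer code, ascending."""
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return np.sort(self._pos[lo:hi])


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling 2-bit codes for every k-window plus a validity mask."""
    n = enc.size
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    m = n - k + 1
    codes = np.zeros(m, dtype=np.int64)
    invalid = np.zeros(m, dtype=bool)
    for j in range(k):
        window = enc[j : j + m]
        codes = (codes << 2) | np.where(window < 4, window, 0)
        invalid |= window >= 4
    return codes, ~invalid


def kmer_codes_of(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Public wrapper: (codes, valid) arrays for all k-windows of seq."""
    return _kmer_codes(encode(seq), k)


@dataclass(frozen=True)
class LocalHit:
    """An ungapped local similarity between a query and a target.

    Intervals are 0-based half-open.  ``strand`` is '+' when the query
    matched in its given orientation and '-' when its reverse complement
    matched; query coordinates always refer to the query as supplied.
    """

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    matches: int

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.length


def best_segments(
    match: np.ndarray, min_len: int, min_frac: float, mismatch_penalty: float = 1.0
) -> list[tuple[int, int, int]]:
    """Maximal-scoring runs in a boolean match vector, then filtered.

    Matches score +1 and mismatches -``mismatch_penalty``; the
    maximal-scoring run is found (Kadane), reported if it is at least
    ``min_len`` long with identity >= ``min_frac``, then masked and the
    search repeated.  A run failing the thresholds is searched for its
    best qualifying sub-window before being discarded, so a diverged
    core inside a longer mediocre run is still found -- but a short
    perfect fragment is never padded with random columns to reach the
    length threshold.  Iteration stops once the best remaining score
    falls below that of a minimally qualifying window.  Returns
    disjoint (start, end, n_matches) tuples sorted by position.
    """
    n = match.size
    if n < min_len:
        return []
    m = match.astype(np.int64)
    vals = np.where(m > 0, 1.0, -float(mismatch_penalty))
    # a window of length min_len at identity exactly min_frac scores:
    floor_score = min_len * (min_frac - mismatch_penalty * (1.0 - min_frac)) - 1e-9
    active = np.ones(n, dtype=bool)
    out: list[tuple[int, int, int]] = []
    while True:
        run = _kadane(vals, active)
        if run is None or run[2] < floor_score:
            break
        s, e, _score = run
        nm = int(m[s:e].sum())
        if e - s >= min_len and nm >= min_frac * (e - s) - 1e-9:
            out.append((s, e, nm))
        else:
            sub = _best_qualifying_subwindow(
                m[s:e], vals[s:e], min_len, min_frac
            )
            if sub is not None:
                out.append((sub[0] + s, sub[1] + s, sub[2]))
        active[s:e] = False
    out.sort()
    return out


def _kadane(vals: np.ndarray, active: np.ndarray):
    """Maximum-sum subarray over active positions; None if all masked.

    Prefix-sum formulation: the best subarray ending at e has sum
    pref[e] - min(pref[:e]); masked positions carry a huge negative
    value, so no optimal run crosses them.
    """
    v = np.where(active, vals, -(10.0**9))
    pref = np.concatenate(([0.0], np.cumsum(v)))
    run_min = np.minimum.accumulate(pref[:-1])
    gains = pref[1:] - run_min
    e_idx = int(np.argmax(gains))
    best_sum = float(gains[e_idx])
    if best_sum <= 0:
        return None
    s = int(np.nonzero(pref[: e_idx + 1] <= run_min[e_idx] + 1e-12)[0][0])
    return (s, e_idx + 1, best_sum)


def _best_qualifying_subwindow(m, vals, min_len, min_frac):
    """Best (score-max) window with len >= min_len, identity >= min_frac,
    confined to one maximal run (quadratic in the run length)."""
    n = m.size
    if n < min_len:
        return None
    pref = np.concatenate(([0.0], np.cumsum(vals)))
    pref_m = np.concatenate(([0], np.cumsum(m)))
    best = None
    for s in range(0, n - min_len + 1):
        ends = np.arange(s + min_len, n + 1)
        scores = pref[ends] - pref[s]
        nmatch = pref_m[ends] - pref_m[s]
        ok = nmatch >= min_frac * (ends - s) - 1e-9
        if not ok.any():
            continue
        idx = np.nonzero(ok)[0]
        smax = scores[idx].max()
        cand = idx[np.nonzero(scores[idx] >= smax - 1e-9)[0][-1]]  # longest
        e = int(ends[cand])
        key = (float(scores[cand]), e - s, -s)
        if best is None or key > best[0]:
            best = (key, s, e, int(nmatch[cand]))
    if best is None:
        return None
    _, s, e, nm = best
    return (s, e, nm)


def local_hits(
    query: str,
    target_index: KmerIndex,
    target_enc: np.ndarray,
    *,
    min_len: int = 50,
    min_identity: float = 80.0,
    seed_k: int = 10,
    both_strands: bool = True,
    exclude_self_diagonal: bool = False,
    merge: bool = True,
    mismatch_penalty: float = 2.0,
) -> list[LocalHit]:
    """Ungapped local matches of ``query`` against an indexed target.

    Seeds exact ``seed_k``-mers shared by query and target, extends each
    seeded diagonal into maximal-scoring windows with identity >=
    min_identity over >= min_len, and merges overlapping reports
    keeping the best-scoring one.  With ``both_strands`` the reverse
    complement of the query is scanned too.  The default mismatch
    penalty of 2 keeps extension into random flanking sequence (match
    density 1/4) strongly disfavoured, so hit boundaries rarely
    overshoot the true end of a repeat by more than a few bases.
    """
    n_t = target_enc.size
    hits: list[LocalHit] = []
    orientations = [("+", query)]
    if both_strands:
        orientations.append(("-", revcomp(query)))
    for strand, q in orientations:
        q_enc = encode(q)
        codes, valid = _kmer_codes(q_enc, target_index.k)
        diagonals: set[int] = set()
        for qpos in np.nonzero(valid)[0]:
            for tpos in target_index.lookup(int(codes[qpos])):
                diagonals.add(int(tpos) - int(qpos))
        for d in sorted(diagonals):
            if exclude_self_diagonal and strand == "+" and d == 0:
                continue
            q_lo = max(0, -d)
            q_hi = min(len(q), n_t - d)
            if q_hi - q_lo < min_len:
                continue
            match = q_enc[q_lo:q_hi] == target_enc[q_lo + d : q_hi + d]
            # non-ACGT never matches
            match &= q_enc[q_lo:q_hi] < 4
            for s, e, nm in best_segments(
                match, min_len, min_identity / 100.0, mismatch_penalty
            ):
                qs, qe = q_lo + s, q_lo + e
                ts, te = qs + d, qe + d
                if strand == "-":
                    qs, qe = len(q) - qe, len(q) - qs
                hits.append(LocalHit(qs, qe, ts, te, strand, int(nm)))
    if not merge:
        hits.sort(key=lambda h: (h.t_start, h.t_end, h.strand))
        return hits
    return merge_overlapping_hits(hits)


def merge_overlapping_hits(hits: list[LocalHit]) -> list[LocalHit]:
    """Drop hits whose target interval mostly overlaps a better hit.

    Two hits conflict when their target intervals overlap by more than
    half of the shorter one; the hit with more matches (then greater
    length, then leftmost) wins.  Output sorted by target position.
    """
    kept: list[LocalHit] = []
    for h in sorted(hits, key=lambda h: (-h.matches, -(h.length), h.t_start)):
        clash = False
        for g in kept:
            ov = min(h.t_end, g.t_end) - max(h.t_start, g.t_start)
            if ov > 0.5 * min(h.t_end - h.t_start, g.t_end - g.t_start):
                clash = True
                break
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: (h.t_start, h.t_end, h.strand))
    return kept
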