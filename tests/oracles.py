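"""Independent oracles: brute-force counterparts of the fast paths.

These implementations deliberately share no search code with the
package: the inverted-repeat oracle scans every anti-diagonal with a
prefix-sum argmax, the TSD oracle enumerates every window pair, and
expected distances come from direct formula evaluation.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")
_CODE = {b: i for i, b in enumerate("ACGT")}


def oracle_inverted_repeats(seq, min_len=100, min_identity=80.0, max_span=20000):
    """Best qualifying window per anti-diagonal, exhaustively.

    For every anti-diagonal D, positions x pair with D - x; the longest
    window of length >= min_len with match fraction >= min_identity is
    located with a prefix-sum / running-minimum scan (O(n) per
    diagonal, O(n^2) total).  Returns (left, right) interval pairs.
    """
    n = len(seq)
    p = min_identity / 100.0
    enc = np.array([_CODE.get(b, -9) for b in seq.upper()])
    out = []
    for D in range(2 * min_len - 1, 2 * n - 2):
        x_hi = min((D - 1) // 2, n - 1)
        x_lo = max(0, D - n + 1, (D + 2 - max_span) // 2)
        if x_hi - x_lo + 1 < min_len:
            continue
        xs = np.arange(x_lo, x_hi + 1)
        a, b = enc[xs], enc[D - xs]
        m = ((a + b) == 3) & (a >= 0) & (b >= 0)
        t = m.astype(float) - p
        pref = np.concatenate(([0.0], np.cumsum(t)))
        L = t.size
        run_min = np.minimum.accumulate(pref[: L - min_len + 1])
        gains = pref[min_len:] - run_min
        if not np.any(gains >= -1e-9):
            continue
        # longest qualifying window: largest e - argmin_s among feasible
        best = None
        for e in np.nonzero(gains >= -1e-9)[0]:
            end = e + min_len
            s_candidates = np.nonzero(pref[: end - min_len + 1] <= pref[end] + 1e-9)[0]
            s = int(s_candidates[0])
            if best is None or end - s > best[1] - best[0]:
                best = (s, end)
        s, e = best
        ls, le = x_lo + s, x_lo + e
        out.append(((ls, le), (D - le + 1, D - ls + 1)))
    return out


def has_qualifying_pair(seq, **kw) -> bool:
    return bool(oracle_inverted_repeats(seq, **kw))


def oracle_tsd(seq, lb, rb, len_range=(9, 11), max_mismatch=2, tol=2):
    """All qualifying TSD windows, ranked by the package's ordering.

    Returns the best (length, mismatches, left_start, right_start) or
    None; ordering = fewest mismatches, most exact abutment, longest.
    """
    cands = []
    for length in range(len_range[0], len_range[1] + 1):
        for off_l in range(-tol, tol + 1):
            ls = lb + off_l - length
            le = lb + off_l
            if ls < 0 or le > len(seq):
                continue
            left = seq[ls:le].upper()
            for off_r in range(-tol, tol + 1):
                rs = rb + off_r
                re = rs + length
                if rs < 0 or re > len(seq):
                    continue
                right = seq[rs:re].upper()
                mism = sum(
                    1 for x, y in zip(left, right) if x != y or x not in "ACGT"
                )
                if mism <= max_mismatch:
                    cands.append(
                        (
                            (mism, abs(off_l) + abs(off_r), -length,
                             abs(off_l), off_l, off_r),
                            (length, mism, ls, rs),
                        )
                    )
    if not cands:
        return None
    return min(cands)[1]


def skbio_splits(matrix: np.ndarray, labels: list[str]) -> set[frozenset]:
    """Nontrivial bipartitions of scikit-bio's NJ tree."""
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sknj

    tree = sknj(SkDM(matrix, ids=labels))
    allset = frozenset(labels)
    ref = min(labels)
    out = set()
    for node in tree.non_tips():
        below = frozenset(leaf.name for leaf in node.tips())
        side = allset - below if ref in below else below
        if 1 < len(side) < len(labels) - 1:
            out.add(side)
    return out
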