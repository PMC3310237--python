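"""TIR phylogenetics, conservation profiling, and repeat-motif search.

Distances between aligned sequences use the Kimura two-parameter model,
which separates transitions (A<->G, C<->T) from transversions; trees
are built with neighbor joining and assessed by column-resampling
bootstrap with a majority-rule consensus.  Conservation along a family
is summarised as the fraction of copies matching the column consensus,
averaged over 5-column windows.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import encode, percent_identity, revcomp
from . import alignment as _aln

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


class SaturationError(ValueError):
    """K2P distance undefined: substitution fractions beyond saturation."""


def k2p_distance(a: str, b: str) -> float:
    """Kimura two-parameter distance between two aligned sequences.

    Columns where either sequence has a gap or ambiguous base are
    excluded.  With P the transition and Q the transversion fraction,
    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)).  Saturated pairs raise
    SaturationError rather than returning NaN.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    n = p = q = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            p += 1
        else:
            q += 1
    if n == 0:
        raise ValueError("no alignable columns")
    P, Q = p / n, q / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated: P={P:.3f}, Q={Q:.3f}")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def _k2p_pairwise(enc: np.ndarray, saturation_cap: float | None) -> np.ndarray:
    """Vectorised pairwise K2P over an encoded (taxa x columns) matrix.

    Codes >= 4 (gaps, ambiguous) exclude a column for that pair; with
    the A,C,G,T -> 0..3 encoding, transitions are unequal codes of
    equal parity.
    """
    n = enc.shape[0]
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = enc[i], enc[j]
        ok = (a < 4) & (b < 4)
        m = int(ok.sum())
        if m == 0:
            raise ValueError("no alignable columns")
        diff = ok & (a != b)
        ts = diff & ((a % 2) == (b % 2))
        P = int(ts.sum()) / m
        Q = int(diff.sum() - ts.sum()) / m
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        if w1 <= 0 or w2 <= 0:
            if saturation_cap is None:
                raise SaturationError(f"saturated: P={P:.3f}, Q={Q:.3f}")
            dist = saturation_cap
        else:
            dist = -0.5 * math.log(w1 * math.sqrt(w2))
        d[i, j] = d[j, i] = dist
    return d


def k2p_matrix(
    seqs: dict[str, str], saturation_cap: float | None = None
) -> "DistanceMatrix":
    """Pairwise K2P distances for a set of aligned sequences.

    ``saturation_cap`` substitutes a finite distance for saturated
    pairs; when None, saturation propagates as SaturationError.
    """
    labels = list(seqs)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    enc = np.stack([encode(seqs[lab]) for lab in labels])
    return DistanceMatrix(labels, _k2p_pairwise(enc, saturation_cap))


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with taxon labels."""

    labels: list[str]
    data: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("entries must be finite and nonnegative")
        self.data = d


@dataclass
class TreeNode:
    """Node of an (unrooted, trifurcating-root) phylogenetic tree."""

    label: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(lf.label for lf in self.leaves())

    def newick(self, with_support: bool = False) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return f"{node.label}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            lab = ""
            if with_support and node.support is not None:
                lab = f"{node.support:.0f}"
            return f"({inner}){lab}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"

    def splits(self) -> dict[frozenset[str], float]:
        """Nontrivial bipartitions (as the child-side leaf set) with
        branch support, canonicalised to the side not containing the
        lexicographically smallest taxon."""
        all_leaves = self.leaf_names()
        ref = min(all_leaves)
        out: dict[frozenset[str], float] = {}

        def walk(node: TreeNode):
            for c in node.children:
                if not c.is_leaf():
                    below = c.leaf_names()
                    side = all_leaves - below if ref in below else below
                    if 1 < len(side) < len(all_leaves) - 1:
                        out[side] = c.support if c.support is not None else np.nan
                walk(c)

        walk(self)
        return out

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""

        def find(node, name, acc):
            if node.is_leaf():
                return acc + [node] if node.label == name else None
            for c in node.children:
                r = find(c, name, acc + [node])
                if r:
                    return r
            return None

        pa = find(self, a, [])
        pb = find(self, b, [])
        shared = 0
        for x, y in zip(pa, pb):
            if x is y:
                shared += 1
            else:
                break
        return sum(n.length for n in pa[shared:]) + sum(n.length for n in pb[shared:])


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree with deterministic tie-breaking.

    The pair minimising the Q criterion is joined at each step, ties
    resolved by smallest (i, j) index pair; negative branch lengths are
    clamped to zero with the deficit transferred to the sibling branch.
    With fewer than 3 taxa a degenerate tree is returned with a
    warning.
    """
    labels = list(dm.labels)
    if len(labels) < 3:
        warnings.warn("fewer than 3 taxa: degenerate tree", stacklevel=2)
        root = TreeNode()
        d = float(dm.data[0, 1]) if len(labels) == 2 else 0.0
        for lab in labels:
            root.children.append(TreeNode(label=lab, length=d / 2))
        return root

    nodes = [TreeNode(label=lab) for lab in labels]
    D = dm.data.astype(float).copy()
    active = list(range(len(labels)))
    next_rows = {i: nodes[i] for i in active}

    while len(active) > 3:
        n = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(n):
            for aj in range(ai + 1, n):
                i, j = active[ai], active[aj]
                q = (n - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        ci, cj = next_rows[i], next_rows[j]
        ci.length, cj.length = li, lj
        parent.children = [ci, cj]
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        next_rows[i] = parent
        active.remove(j)

    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = TreeNode()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        child = next_rows[idx]
        child.length = max(ln, 0.0)
        root.children.append(child)
    return root


def bootstrap_replicate_indices(
    n_cols: int, n_reps: int, seed: int
) -> np.ndarray:
    """Column index matrix (n_reps x n_cols) for bootstrap resampling."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, n_cols, size=(n_reps, n_cols))


def bootstrap_support(
    alignment: dict[str, str],
    n_reps: int = 1000,
    seed: int = 0,
    consensus_threshold: float = 0.40,
    saturation_cap: float = 5.0,
) -> TreeNode:
    """Majority-rule consensus tree with bootstrap split support.

    Resamples alignment columns with replacement, rebuilds an NJ tree
    per replicate, and retains splits whose frequency reaches
    ``consensus_threshold`` (greedily, most frequent first, keeping
    only mutually compatible splits).  Support values are percentages.
    """
    labels = list(alignment)
    if len(labels) < 4:
        raise ValueError("bootstrap requires >= 4 taxa")
    enc = np.stack([encode(alignment[lab]) for lab in labels])
    n_cols = enc.shape[1]
    idx = bootstrap_replicate_indices(n_cols, n_reps, seed)
    counts: dict[frozenset[str], int] = {}
    for rep in range(n_reps):
        dm = DistanceMatrix(
            labels, _k2p_pairwise(enc[:, idx[rep]], saturation_cap)
        )
        tree = nj_tree(dm)
        for split in tree.splits():
            counts[split] = counts.get(split, 0) + 1

    freq = {s: 100.0 * c / n_reps for s, c in counts.items()}
    chosen: list[tuple[frozenset[str], float]] = []
    for s, f in sorted(freq.items(), key=lambda kv: (-kv[1], sorted(kv[0]))):
        if f < 100.0 * consensus_threshold:
            continue
        if all(_compatible(s, t) for t, _ in chosen):
            chosen.append((s, f))
    return _tree_from_splits(set(labels), chosen)


def _compatible(a: frozenset[str], b: frozenset[str]) -> bool:
    return a <= b or b <= a or not (a & b)


def _tree_from_splits(
    taxa: set[str], splits: list[tuple[frozenset[str], float]]
) -> TreeNode:
    root = TreeNode()
    root.children = [TreeNode(label=t) for t in sorted(taxa)]
    for s, support in sorted(splits, key=lambda kv: -len(kv[0])):
        node = root
        while True:
            host = next(
                (
                    c
                    for c in node.children
                    if not c.is_leaf() and s <= c.leaf_names()
                ),
                None,
            )
            if host is None:
                break
            node = host
        grouped = [c for c in node.children if c.leaf_names() <= s]
        if len(grouped) < 2:
            continue
        new = TreeNode(support=support, length=1.0)
        new.children = grouped
        node.children = [c for c in node.children if c not in grouped] + [new]
        node.children.sort(key=lambda c: min(c.leaf_names()))
    return root


@dataclass
class WindowSeq:
    """A TIR window oriented 5'->3' into the element."""

    label: str
    sequence: str
    truncated: bool = False


def extract_windows(
    elements,
    genome: str,
    end: str,
    role: str,
    width: int,
) -> list[WindowSeq]:
    """Width-limited TIR slices for alignment and tree building.

    ``end`` is 'left'/'right' in element orientation (5'/3'),
    ``role`` one of external/internal/solo.  Windows are read 5'->3'
    into the element regardless of the element's genomic orientation;
    labels follow the 5'-Ex / 3'-In convention.  TIRs shorter than
    ``width`` are returned whole with a truncation flag.
    """
    if end not in ("left", "right"):
        raise ValueError("end must be 'left' or 'right'")
    out: list[WindowSeq] = []
    for e in elements:
        flipped = e.strand == "-"
        want_end = end if not flipped else ("right" if end == "left" else "left")
        cands = [(h, r) for h, r in e.tirs if r == role]
        if not cands:
            continue
        mid = (e.start + e.end) / 2
        if want_end == "left":
            hit = min(cands, key=lambda hr: hr[0].start)[0]
        else:
            hit = max(cands, key=lambda hr: hr[0].end)[0]
        seq = genome[hit.start : hit.end].upper()
        # orient 5'->3' pointing into the element
        genome_left_end = hit.start + hit.end < 2 * mid
        if not genome_left_end:
            seq = revcomp(seq)
        truncated = len(seq) < width
        seq = seq[:width]
        prime = "5'" if end == "left" else "3'"
        tag = {"external": "Ex", "internal": "In", "solo": "So"}.get(role, role)
        out.append(WindowSeq(f"{e.element_id}_{prime}-{tag}", seq, truncated))
    return out


@dataclass
class ConservationProfile:
    """Mean per-window consensus-match scores along an alignment."""

    scores: np.ndarray  # one value per 5-column window, in [0, 1]
    window: int
    starts: np.ndarray  # alignment-column start of each window

    def mean(self) -> float:
        return float(self.scores.mean())


def conservation_profile(
    copies: list[str] | dict[str, str],
    first_n: int = 700,
    window: int = 5,
) -> ConservationProfile:
    """Windowed conservation across the copies of a family.

    The first ``first_n`` bases of each copy are aligned to a reference
    (the copy with highest mean identity to the others), a consensus is
    called, copies are re-projected onto it, and each column is scored
    as the fraction of copies matching the column consensus (gaps count
    as mismatches).  Scores are averaged over successive ``window``
    columns.
    """
    if isinstance(copies, dict):
        seqs = [s.upper()[:first_n] for s in copies.values()]
    else:
        seqs = [s.upper()[:first_n] for s in copies]
    if len(seqs) < 2:
        raise ValueError("conservation profile requires at least 2 copies")

    def project(ref: str) -> np.ndarray:
        """Character matrix of all copies on reference coordinates."""
        import edlib

        mat = np.full((len(seqs), len(ref)), "-", dtype="U1")
        for i, s in enumerate(seqs):
            res = edlib.align(s, ref, mode="NW", task="path")
            qi = ti = 0
            for ncols, op in _aln._CIGAR_RE.findall(res["cigar"]):
                ncols = int(ncols)
                if op in ("=", "X", "M"):
                    for k in range(ncols):
                        mat[i, ti + k] = s[qi + k]
                    qi += ncols
                    ti += ncols
                elif op == "I":  # insertion in copy relative to reference
                    qi += ncols
                elif op == "D":
                    ti += ncols
        return mat

    # reference = copy with highest mean identity to the others
    ident = np.zeros(len(seqs))
    for i, j in itertools.combinations(range(len(seqs)), 2):
        pid = percent_identity(seqs[i], seqs[j])
        ident[i] += pid
        ident[j] += pid
    ref_idx = int(np.argmax(ident))

    def consensus_of(mat: np.ndarray) -> str:
        # majority base per column; gaps never win unless a column is
        # all-gap, so a gap always scores as a mismatch
        cons = []
        for col in mat.T:
            vals, cnt = np.unique(col, return_counts=True)
            order = sorted((-c, v) for c, v in zip(cnt, vals) if v != "-")
            cons.append(order[0][1] if order else "-")
        return "".join(cons)

    mat = project(seqs[ref_idx])
    cons = consensus_of(mat).replace("-", "")
    mat = project(cons or seqs[ref_idx])  # second pass against consensus
    cons2 = consensus_of(mat)
    col_scores = (mat == np.array(list(cons2))).mean(axis=0)

    n_win = math.ceil(col_scores.size / window)
    scores = np.array(
        [col_scores[w * window : (w + 1) * window].mean() for w in range(n_win)]
    )
    starts = np.arange(n_win) * window
    return ConservationProfile(scores, window, starts)


@dataclass(frozen=True)
class MotifPair:
    """A direct-repeat motif pair inside a single sequence."""

    first: tuple[int, int]
    second: tuple[int, int]
    matches: int

    @property
    def length(self) -> int:
        return self.first[1] - self.first[0]

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.length


def find_internal_repeats(
    tir: str, min_len: int = 15, min_identity: float = 80.0, seed_k: int = 8
) -> list[MotifPair]:
    """Direct-repeat motifs inside one TIR sequence.

    Self-alignment excluding the trivial diagonal, reporting interval
    pairs with identity >= min_identity over >= min_len, deduplicated
    to first-interval-before-second.
    """
    from .alignment import KmerIndex, local_hits

    if len(tir) < 2 * min_len:
        return []
    k = min(seed_k, min_len)
    idx = KmerIndex(tir, k)
    enc = encode(tir)
    pairs = []
    seen = set()
    for h in local_hits(
        tir, idx, enc,
        min_len=min_len, min_identity=min_identity, seed_k=k,
        both_strands=False, exclude_self_diagonal=True, merge=False,
    ):
        first = (h.q_start, h.q_end)
        second = (h.t_start, h.t_end)
        if second < first:
            first, second = second, first
        if first == second:
            continue
        key = (first, second)
        if key not in seen:
            seen.add(key)
            pairs.append(MotifPair(first, second, h.matches))
    pairs.sort(key=lambda p: (p.first, p.second))
    return pairs
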