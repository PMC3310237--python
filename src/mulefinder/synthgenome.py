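"""Seeded synthetic genomes with implanted MULE-like elements.

The generator emulates the element structures the annotation pipeline is
designed to detect: long terminal inverted repeats (TIRs) of 50-600 bp,
9-11 bp target-site duplications (TSDs) created by duplicating the
insertion site, tandem or solo extra TIRs in six architectures, captured
cargo fragments, transposase-coding internal regions, terminal
truncations, point-mutation copy families, and nested insertions of
foreign repeats.  Every implanted feature is reported in a TruthRecord
with exact coordinates in the output genome, which serves as the oracle
for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import revcomp

ARCHITECTURES = ("single", "type1", "type2", "type3", "type4", "type5", "type6")

#: architectures whose extra TIRs sit in tandem with an external TIR
TANDEM_TYPES = ("type1", "type2", "type3")
#: architectures with a solo TIR in the interior of the element
INTERIOR_SOLO_TYPES = ("type4", "type5", "type6")

_BASES = np.array(list("ACGT"))
_AA = list("ACDEFGHIKLMNPQRSTVWY")
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}


class SimulationError(Exception):
    """Raised when a genome cannot be simulated as requested."""


@dataclass(frozen=True)
class GenomeSpec:
    """Random background sequence: i.i.d. bases at a given GC fraction."""

    length: int
    gc: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"genome length must be positive, got {self.length}")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"gc must be in [0, 1], got {self.gc}")


@dataclass(frozen=True)
class ElementSpec:
    """One element family to implant.

    ``tir_seq`` is the family TIR read 5'->3' from the element's outer
    edge inward; every arm of every copy derives from it.  The internal
    region (``internal_seq``) sits between the innermost arms; cargo /
    transposase intervals are given relative to it.  For the interior
    solo architectures (type4-6) the solo arm is inserted near the
    midpoint of the internal region, which must leave more than 600 bp
    between the solo arm and each external TIR.  ``tir_spacing``
    applies only to tandem architectures (type1-3).
    """

    architecture: str
    tir_seq: str
    internal_seq: str
    family: str = "SYN-MULE01"
    tir_arm_identity: float = 1.0
    tir_spacing: int = 100
    spacer_seq: str = ""
    cargo_interval: tuple[int, int] | None = None
    transposase_interval: tuple[int, int] | None = None
    tsd_len: int = 9
    tsd_seq: str | None = None
    truncation_left: int = 0
    truncation_right: int = 0
    n_copies: int = 1
    copy_divergence: float = 0.0
    nested_seq: str | None = None
    #: optional per-copy (left, right) external truncations applied on top
    #: of the ancestral element; length must equal n_copies when given
    copy_truncations: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if len(self.tir_seq) < 50:
            raise ValueError("tir_seq must be at least 50 bases")
        if not 9 <= self.tsd_len <= 11:
            raise ValueError("tsd_len must be in [9, 11]")
        if self.architecture in TANDEM_TYPES and not 0 < self.tir_spacing < 600:
            raise ValueError("tir_spacing must be in (0, 600) for tandem types")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        if not 0.0 < self.tir_arm_identity <= 1.0:
            raise ValueError("tir_arm_identity must be in (0, 1]")
        if self.tsd_seq is not None and len(self.tsd_seq) != self.tsd_len:
            raise ValueError("tsd_seq length must equal tsd_len")
        if (
            self.copy_truncations is not None
            and len(self.copy_truncations) != self.n_copies
        ):
            raise ValueError("copy_truncations must list one pair per copy")


@dataclass(frozen=True)
class ArmTruth:
    """One TIR arm of an implanted element (0-based half-open)."""

    start: int
    end: int
    role: str  # external_tir | internal_tir | solo_tir
    orientation: str  # '+' = as tir_seq, '-' = reverse complement


@dataclass
class TruthRecord:
    """Ground truth for one implanted element copy."""

    element_id: str
    family: str
    architecture: str
    start: int
    end: int
    arms: list[ArmTruth]
    tsd_seq: str
    tsd_left: tuple[int, int]
    tsd_right: tuple[int, int]
    cargo: tuple[int, int] | None = None
    transposase: tuple[int, int] | None = None
    nested: tuple[int, int] | None = None

    def shifted(self, offset: int) -> "TruthRecord":
        def sh(iv):
            return None if iv is None else (iv[0] + offset, iv[1] + offset)

        return TruthRecord(
            element_id=self.element_id,
            family=self.family,
            architecture=self.architecture,
            start=self.start + offset,
            end=self.end + offset,
            arms=[replace(a, start=a.start + offset, end=a.end + offset)
                  for a in self.arms],
            tsd_seq=self.tsd_seq,
            tsd_left=sh(self.tsd_left),
            tsd_right=sh(self.tsd_right),
            cargo=sh(self.cargo),
            transposase=sh(self.transposase),
            nested=sh(self.nested),
        )


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def encode_protein(protein: str, rng: np.random.Generator) -> str:
    """A nucleotide ORF coding for ``protein`` with random codon choice."""
    return "".join(_CODONS[a][rng.integers(len(_CODONS[a]))] for a in protein)


def mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Apply exactly ``n_subs`` substitutions at distinct positions."""
    if n_subs == 0:
        return seq
    arr = np.array(list(seq))
    pos = rng.choice(len(seq), size=min(n_subs, len(seq)), replace=False)
    for p in pos:
        alternatives = [b for b in "ACGT" if b != arr[p]]
        arr[p] = alternatives[rng.integers(3)]
    return "".join(arr)


def diverge(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Point-mutate each site independently with probability ``rate``."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(seq)) < rate
    for p in np.nonzero(hit)[0]:
        alternatives = [b for b in "ACGT" if b != arr[p]]
        arr[p] = alternatives[rng.integers(3)]
    return "".join(arr)


def generate_background(spec: GenomeSpec) -> str:
    """Background genome: length bases, i.i.d., P(G)+P(C)=gc, seeded."""
    rng = np.random.default_rng(spec.seed)
    return random_seq(rng, spec.length, spec.gc)


def _arm_variant(spec: ElementSpec, rng: np.random.Generator) -> str:
    """A copy of the family TIR at the requested arm identity."""
    n_subs = round((1.0 - spec.tir_arm_identity) * len(spec.tir_seq))
    return mutate(spec.tir_seq, n_subs, rng)


def build_element(
    spec: ElementSpec, seed: int | np.random.Generator = 0
) -> tuple[str, TruthRecord]:
    """Assemble one ancestral element copy and its truth template.

    Coordinates in the returned TruthRecord are element-relative
    (0-based half-open, TSD fields unfilled); ``implant`` shifts them
    into genome space and fills the TSD.  The left external arm is kept
    verbatim as ``tir_seq`` (minus truncation); all other arms are
    independent variants at ``tir_arm_identity``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arch = spec.architecture
    L = len(spec.tir_seq)

    def spacer() -> str:
        if spec.spacer_seq:
            return spec.spacer_seq
        return random_seq(rng, spec.tir_spacing)

    internal = spec.internal_seq
    cargo = spec.cargo_interval
    transposase = spec.transposase_interval
    nested = None
    if spec.nested_seq is not None:
        mid = len(internal) // 2
        internal = internal[:mid] + spec.nested_seq + internal[mid:]
        nested = (mid, mid + len(spec.nested_seq))

        def bump(iv):
            if iv is None:
                return None
            s, e = iv
            if s >= mid:
                return (s + len(spec.nested_seq), e + len(spec.nested_seq))
            return iv

        cargo = bump(cargo)
        transposase = bump(transposase)

    # parts: (sequence, role or annotation kind, orientation)
    parts: list[tuple[str, str | None, str]] = []
    ext_left = spec.tir_seq[spec.truncation_left:]
    right_var = _arm_variant(spec, rng)
    ext_right = revcomp(right_var)
    if spec.truncation_right:
        ext_right = ext_right[: len(ext_right) - spec.truncation_right]

    parts.append((ext_left, "external_tir", "+"))
    if arch in ("type1", "type2"):
        parts.append((spacer(), None, "+"))
        parts.append((_arm_variant(spec, rng), "internal_tir", "+"))
        parts.append((internal, "internal", "+"))
        parts.append((revcomp(_arm_variant(spec, rng)), "internal_tir", "-"))
        parts.append((spacer(), None, "+"))
    elif arch == "type3":
        parts.append((spacer(), None, "+"))
        parts.append((_arm_variant(spec, rng), "solo_tir", "+"))
        parts.append((internal, "internal", "+"))
    elif arch in INTERIOR_SOLO_TYPES:
        solo_mid = len(internal) // 2
        # never split an annotated interval with the solo arm
        for iv in (cargo, transposase, nested):
            if iv is not None and iv[0] < solo_mid < iv[1]:
                solo_mid = iv[1]
        solo = _arm_variant(spec, rng)
        if min(solo_mid, len(internal) - solo_mid) <= 600 + L:
            raise SimulationError(
                "internal region too short to keep the interior solo TIR "
                "more than 600 bp away from both external TIRs"
            )
        parts.append((internal[:solo_mid], "internal_a", "+"))
        parts.append((solo, "solo_tir", "+"))
        parts.append((internal[solo_mid:], "internal_b", "+"))
    else:  # single
        parts.append((internal, "internal", "+"))
    parts.append((ext_right, "external_tir", "-"))

    seq_parts: list[str] = []
    arms: list[ArmTruth] = []
    offsets: dict[str, int] = {}
    pos = 0
    for text, kind, orient in parts:
        if kind in ("external_tir", "internal_tir", "solo_tir"):
            arms.append(ArmTruth(pos, pos + len(text), kind, orient))
        elif kind is not None:
            offsets[kind] = pos
        seq_parts.append(text)
        pos += len(text)
    element = "".join(seq_parts)

    def into_element(iv):
        if iv is None:
            return None
        if arch in INTERIOR_SOLO_TYPES:
            s, e = iv
            if s >= solo_mid:  # lies in internal_b, after the solo arm
                off = offsets["internal_b"] - solo_mid
            else:
                off = offsets["internal_a"]
            return (s + off, e + off)
        return (iv[0] + offsets["internal"], iv[1] + offsets["internal"])

    truth = TruthRecord(
        element_id=spec.family,
        family=spec.family,
        architecture=arch,
        start=0,
        end=len(element),
        arms=arms,
        tsd_seq="",
        tsd_left=(0, 0),
        tsd_right=(0, 0),
        cargo=into_element(cargo),
        transposase=into_element(transposase),
        nested=into_element(nested),
    )
    return element, truth


def implant(
    genome: str,
    elements: list[ElementSpec],
    seed: int = 0,
    *,
    min_gap: int = 200,
    max_retries: int = 2000,
) -> tuple[str, list[TruthRecord]]:
    """Insert every copy of every element spec into the background.

    Each copy lands at a uniformly drawn position, no two insertion
    sites closer than ``min_gap``; the ``tsd_len`` bases at the target
    site are duplicated so that identical direct repeats flank the copy
    (the site itself may be overridden via ``tsd_seq``).  Every copy is
    independently point-mutated at ``copy_divergence`` relative to the
    ancestral element, so pairwise copy identity is ~exp(-2 * rate).
    Truth coordinates refer to the returned genome and are exact.
    """
    rng = np.random.default_rng(seed)
    copies: list[tuple[ElementSpec, int, str, TruthRecord]] = []
    total = 0
    for spec in elements:
        ancestor, template = build_element(spec, rng)
        for c in range(spec.n_copies):
            seq = diverge(ancestor, spec.copy_divergence, rng)
            t = replace(template)
            t.arms = list(template.arms)
            t.element_id = f"{spec.family}.{c + 1}"
            if spec.copy_truncations is not None:
                tl, tr = spec.copy_truncations[c]
                if tl or tr:
                    seq = seq[tl : len(seq) - tr]
                    t = _truncate_truth(t, tl, len(seq))
            copies.append((spec, c, seq, t))
            total += len(seq) + spec.tsd_len
    if total >= len(genome):
        raise SimulationError("total implant length exceeds genome length")

    max_tsd = max((s.tsd_len for s, _, _, _ in copies), default=11)
    sites: list[int] = []
    for _ in range(len(copies)):
        placed = False
        for _try in range(max_retries):
            pos = int(rng.integers(min_gap, len(genome) - min_gap - max_tsd))
            if all(abs(pos - s) >= min_gap for s in sites):
                sites.append(pos)
                placed = True
                break
        if not placed:
            raise SimulationError(
                f"could not place {len(copies)} elements with min_gap={min_gap}"
            )

    order = np.argsort(sites, kind="stable")
    out_parts: list[str] = []
    truths: list[TruthRecord] = []
    prev = 0
    shift = 0  # accumulated length added by previous insertions
    for idx in order:
        spec, c, seq, template = copies[idx]
        site = sites[idx]
        tsd = spec.tsd_seq if spec.tsd_seq is not None else genome[site : site + spec.tsd_len]
        tsd = tsd.upper()
        out_parts.append(genome[prev:site])
        left_start = site + shift
        out_parts.append(tsd)
        out_parts.append(seq)
        out_parts.append(tsd)
        elem_start = left_start + spec.tsd_len
        truth = template.shifted(elem_start)
        truth.tsd_seq = tsd
        truth.tsd_left = (left_start, left_start + spec.tsd_len)
        truth.tsd_right = (truth.end, truth.end + spec.tsd_len)
        truths.append(truth)
        prev = site + spec.tsd_len
        shift += len(seq) + spec.tsd_len
    out_parts.append(genome[prev:])
    new_genome = "".join(out_parts)
    assert len(new_genome) == len(genome) + total
    return new_genome, truths


def _truncate_truth(t: TruthRecord, tl: int, new_len: int) -> TruthRecord:
    """Shift a truth template after chopping ``tl`` leading bases and
    clamping the element to ``new_len`` bases."""
    out = t.shifted(-tl)
    out.start = 0
    out.end = new_len
    out.arms = [
        replace(a, start=max(0, a.start), end=min(new_len, a.end))
        for a in out.arms
    ]
    return out


def make_element_spec(
    rng: np.random.Generator,
    architecture: str,
    family: str,
    *,
    tir_len: int = 150,
    internal_len: int = 700,
    tir_arm_identity: float = 1.0,
    tir_spacing: int = 100,
    tsd_len: int = 9,
    n_copies: int = 1,
    copy_divergence: float = 0.0,
    truncation_left: int = 0,
    truncation_right: int = 0,
    cargo_seq: str | None = None,
    transposase_protein: str | None = None,
    nested_seq: str | None = None,
    copy_truncations: tuple[tuple[int, int], ...] | None = None,
    gc: float = 0.5,
) -> ElementSpec:
    """Convenience builder assembling a random internal region.

    Embeds the cargo fragment (and/or an ORF coding for the transposase
    protein) in the interior of a random internal region; for type4-6
    the internal region is grown so the solo arm keeps >600 bp clearance
    from both externals.
    """
    need = internal_len
    if architecture in INTERIOR_SOLO_TYPES:
        need = max(need, 2 * (600 + tir_len + 50))
    inserts = []
    if cargo_seq:
        inserts.append(("cargo", cargo_seq.upper()))
    if transposase_protein:
        inserts.append(("tpase", encode_protein(transposase_protein, rng)))
    base = random_seq(rng, need, gc)
    cargo_iv = tpase_iv = None
    internal = base
    # place inserts in the second half so interior-solo midpoint insertion
    # does not split them
    anchor = (len(base) * 3) // 4
    for kind, ins in inserts:
        internal = internal[:anchor] + ins + internal[anchor:]
        iv = (anchor, anchor + len(ins))
        if kind == "cargo":
            cargo_iv = iv
        else:
            tpase_iv = iv
        anchor = iv[1] + 20
    return ElementSpec(
        architecture=architecture,
        tir_seq=random_seq(rng, tir_len, gc),
        internal_seq=internal,
        family=family,
        tir_arm_identity=tir_arm_identity,
        tir_spacing=tir_spacing,
        cargo_interval=cargo_iv,
        transposase_interval=tpase_iv,
        tsd_len=tsd_len,
        truncation_left=truncation_left,
        truncation_right=truncation_right,
        n_copies=n_copies,
        copy_divergence=copy_divergence,
        nested_seq=nested_seq,
        copy_truncations=copy_truncations,
    )
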