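"""File formats: FASTA in/out, GFF3 / BED / TSV element reports.

Coordinates are 0-based half-open internally; written reports follow
each format's convention (GFF3 1-based inclusive, BED 0-based
half-open), so a catalog row's size equals end - start + 1 in the
1-based TSV output.  All writers emit deterministic row order.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .annotator import ElementRecord
from .synthgenome import TruthRecord


class FastaError(ValueError):
    """Malformed or inconsistent FASTA input."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Order-preserving named sequence set from (optionally gzipped) FASTA.

    Bases are upper-cased; duplicate record ids raise FastaError.
    """
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise FastaError(f"duplicate FASTA id {rec.id!r} in {path}")
            out[rec.id] = str(rec.seq).upper()
    if not out:
        raise FastaError(f"no FASTA records found in {path}")
    return out


def write_fasta(path, records: dict[str, str], width: int = 70) -> None:
    """Write a named sequence set as (optionally gzipped) FASTA."""
    with _open_text(path, "wt") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def span_length_1based(start: int, end: int) -> int:
    """Length of a 1-based inclusive interval: end - start + 1."""
    if end < start:
        raise ValueError("end must be >= start")
    return end - start + 1


def truth_to_bed(truths: list[TruthRecord], chrom: str = "synth1") -> pd.DataFrame:
    """Ground truth as BED6+3 rows (role in {external_tir, internal_tir,
    solo_tir, tsd, cargo, nested}; extra columns architecture, family)."""
    rows = []
    for t in truths:
        feats: list[tuple[int, int, str, str]] = [
            (a.start, a.end, a.role, a.orientation) for a in t.arms
        ]
        feats.append((t.tsd_left[0], t.tsd_left[1], "tsd", "+"))
        feats.append((t.tsd_right[0], t.tsd_right[1], "tsd", "+"))
        if t.cargo:
            feats.append((*t.cargo, "cargo", "+"))
        if t.nested:
            feats.append((*t.nested, "nested", "+"))
        for s, e, role, strand in feats:
            rows.append(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "name": f"{t.element_id}:{role}",
                    "score": 0,
                    "strand": strand,
                    "architecture": t.architecture,
                    "family": t.family,
                    "role": role,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "architecture", "family", "role",
        ],
    )
    return df.sort_values(["start", "end", "name"], kind="stable").reset_index(drop=True)


def elements_to_bed(elements: list[ElementRecord], chrom: str = "synth1") -> pd.DataFrame:
    """Annotated elements as BED6 (0-based half-open)."""
    rows = [
        {
            "chrom": chrom,
            "start": e.start,
            "end": e.end,
            "name": e.element_id,
            "score": 0,
            "strand": e.strand,
        }
        for e in elements
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


def elements_to_gff3(elements: list[ElementRecord], chrom: str = "synth1") -> str:
    """Annotated elements as GFF3 text (1-based inclusive).

    Each element is a transposable_element feature with
    terminal_inverted_repeat, target_site_duplication, and
    sequence_feature (cargo) children.
    """
    lines = ["##gff-version 3"]
    src = "mulefinder"
    for e in elements:
        attrs = (
            f"ID={e.element_id};architecture={e.architecture};family={e.family}"
        )
        if e.copy_family:
            attrs += f";copy_family={e.copy_family}"
        lines.append(
            "\t".join(
                [
                    chrom, src, "transposable_element",
                    str(e.start + 1), str(e.end), ".", e.strand, ".", attrs,
                ]
            )
        )
        for n, (hit, role) in enumerate(e.tirs, 1):
            lines.append(
                "\t".join(
                    [
                        chrom, src, "terminal_inverted_repeat",
                        str(hit.start + 1), str(hit.end), ".", hit.strand, ".",
                        f"ID={e.element_id}.tir{n};Parent={e.element_id};"
                        f"role={role};identity={hit.identity:.1f}",
                    ]
                )
            )
        if e.tsd is not None:
            for tag, (s, t) in (
                ("tsd_l", (e.tsd.left_start, e.tsd.left_end)),
                ("tsd_r", (e.tsd.right_start, e.tsd.right_end)),
            ):
                lines.append(
                    "\t".join(
                        [
                            chrom, src, "target_site_duplication",
                            str(s + 1), str(t), ".", "+", ".",
                            f"ID={e.element_id}.{tag};Parent={e.element_id};"
                            f"sequence={e.tsd.sequence}",
                        ]
                    )
                )
        for n, h in enumerate(e.cargo_hits, 1):
            lines.append(
                "\t".join(
                    [
                        chrom, src, "sequence_feature",
                        str(h.t_start + 1), str(h.t_end), ".",
                        h.strand, ".",
                        f"ID={e.element_id}.cargo{n};Parent={e.element_id};"
                        f"Note=cargo",
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def elements_to_catalog(
    elements: list[ElementRecord], genome: str, chrom: str = "synth1"
) -> pd.DataFrame:
    """Multi-TIR / Pack-MULE catalog TSV (1-based inclusive coordinates).

    Columns: id, chrom, start, end, size, tsd, outer_tir_identity,
    inner_tir_identity; size excludes nested repeats when computed,
    else equals the 1-based span length.
    """
    rows = []
    for e in elements:
        ext_l, ext_r = e.external_hits()
        outer = round(
            _arm_vs_arm_identity(genome, ext_l, ext_r), 0
        )
        inner_hits = [h for h, role in e.tirs if role in ("internal", "solo")]
        if len(inner_hits) == 2:
            inner = round(
                _arm_vs_arm_identity(genome, inner_hits[0], inner_hits[1]), 0
            )
        else:
            inner = None
        size = e.size if e.size is not None else e.span
        rows.append(
            {
                "id": e.element_id,
                "chrom": chrom,
                "start": e.start + 1,
                "end": e.end,
                "size": size,
                "tsd": e.tsd.sequence if e.tsd else "",
                "outer_tir_identity": outer,
                "inner_tir_identity": inner if inner is not None else "N/A",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id", "chrom", "start", "end", "size", "tsd",
            "outer_tir_identity", "inner_tir_identity",
        ],
    )


def _arm_vs_arm_identity(genome: str, left, right) -> float:
    from .alignment import percent_identity, revcomp

    a = genome[left.start : left.end]
    b = genome[right.start : right.end]
    return percent_identity(a, revcomp(b))


def write_outputs(
    elements: list[ElementRecord],
    genome: str,
    out_prefix,
    truths: list[TruthRecord] | None = None,
    chrom: str = "synth1",
) -> dict[str, Path]:
    """Write GFF3 + BED + catalog TSV (and truth BED when given)."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    gff = out_prefix.with_suffix(".gff3")
    gff.write_text(elements_to_gff3(elements, chrom))
    paths["gff3"] = gff
    bed = out_prefix.with_suffix(".bed")
    elements_to_bed(elements, chrom).to_csv(bed, sep="\t", header=False, index=False)
    paths["bed"] = bed
    tsv = out_prefix.with_suffix(".catalog.tsv")
    elements_to_catalog(elements, genome, chrom).to_csv(tsv, sep="\t", index=False)
    paths["catalog"] = tsv
    if truths is not None:
        tbed = Path(str(out_prefix) + ".truth.bed")
        truth_to_bed(truths, chrom).to_csv(tbed, sep="\t", header=False, index=False)
        paths["truth_bed"] = tbed
    return paths
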