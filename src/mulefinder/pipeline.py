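"""Pipeline driver: simulate -> discover -> curate -> annotate -> report.

Ties the stages together behind one seeded, deterministic entry point:
identical config and seed produce byte-identical output files.  Stage
logs record candidate / accepted / rejected counts so the filtering is
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotator, evolution, fastaio, irfinder, synthgenome, tirlib
from .config import PipelineConfig


@dataclass
class PipelineResult:
    genome: str
    truths: list | None
    library: list[tirlib.TirFamily]
    elements: list[annotator.ElementRecord]
    orphans: list
    rejects: list
    family_table: pd.DataFrame
    size_counts: np.ndarray | None = None
    size_excluded: int = 0
    conservation: evolution.ConservationProfile | None = None
    tree: evolution.TreeNode | None = None
    log: list[str] = field(default_factory=list)
    out_paths: dict = field(default_factory=dict)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def demo_element_specs(seed: int, gc: float = 0.42):
    """Element families for a simulated demo genome.

    One family per architecture: Pack-MULE cargo in type1/type5, a
    transposase ORF in type6, one nested foreign repeat in the single
    family, TSD lengths cycling over 9-11, arm identity 95%, copies
    diverged by 3% point mutation.  Returns (specs, cargo library,
    protein library, repeat library).
    """
    rng = np.random.default_rng(seed)
    cargo = {"CARGO-ZIBP": synthgenome.random_seq(rng, 320, gc)}
    protein = {"TPASE-1": synthgenome.random_protein(rng, 220)}
    foreign = {"FOREIGN-LTR": synthgenome.random_seq(rng, 400, gc)}
    copies = {"single": 3, "type1": 4, "type2": 4, "type3": 3,
              "type4": 3, "type5": 3, "type6": 2}
    specs = []
    for i, (arch, n) in enumerate(copies.items()):
        specs.append(
            synthgenome.make_element_spec(
                rng, arch, f"FAM{i + 1:02d}",
                tir_len=150, internal_len=700,
                tir_arm_identity=0.95, tir_spacing=100,
                tsd_len=9 + i % 3, n_copies=n, copy_divergence=0.03,
                cargo_seq=cargo["CARGO-ZIBP"] if arch in ("type1", "type5") else None,
                transposase_protein=protein["TPASE-1"] if arch == "type6" else None,
                nested_seq=foreign["FOREIGN-LTR"] if arch == "single" else None,
                gc=gc,
            )
        )
    return specs, cargo, protein, foreign


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage under one configuration.

    Stages: simulate (optional) -> inverted-repeat discovery -> library
    curation -> genome scan -> element assembly/classification -> copy
    grouping -> autonomy and size -> conservation and phylogeny ->
    report files under ``cfg.out_dir``.
    """
    log: list[str] = []
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    # --- inputs -----------------------------------------------------
    truths = None
    cargo_lib: dict[str, str] = {}
    protein_lib: dict[str, str] = {}
    repeat_lib: dict[str, str] = {}
    if cfg.simulate:
        def simulate():
            specs, cargo, protein, foreign = demo_element_specs(
                cfg.seed, cfg.genome_gc
            )
            # background and implant sites use sub-seeds distinct from
            # the element-spec stream so no spec sequence leaks into
            # the background
            bg = synthgenome.generate_background(
                synthgenome.GenomeSpec(
                    cfg.genome_length, cfg.genome_gc, cfg.seed + 1
                )
            )
            return (*synthgenome.implant(bg, specs, seed=cfg.seed + 2),
                    cargo, protein, foreign)

        genome, truths, cargo_lib, protein_lib, repeat_lib = stage("simulate")(simulate)
        log.append(f"simulate: {len(truths)} copies implanted, genome {len(genome)} bp")
    else:
        if not cfg.genome_fasta:
            raise PipelineError("stage 'input' failed: no genome_fasta and simulate=off")
        genome = "".join(fastaio.read_fasta(cfg.genome_fasta).values())
        log.append(f"input: genome {len(genome)} bp from {cfg.genome_fasta}")
        if cfg.cargo_fasta:
            cargo_lib = fastaio.read_fasta(cfg.cargo_fasta)
        if cfg.transposase_fasta:
            protein_lib = fastaio.read_fasta(cfg.transposase_fasta)
        if cfg.repeat_fasta:
            repeat_lib = fastaio.read_fasta(cfg.repeat_fasta)

    # --- inverted repeats -------------------------------------------
    pairs = stage("irfinder")(
        lambda: irfinder.find_inverted_repeats(
            genome,
            min_len=cfg.min_ir_len,
            min_identity=cfg.min_ir_identity,
            max_span=cfg.max_span,
            seed_k=cfg.ir_seed_k,
        )
    )
    log.append(f"irfinder: {len(pairs)} candidate pairs")

    # --- library curation -------------------------------------------
    def build_library():
        curated = []
        reject_counts: dict[str, int] = {}
        for p in pairs:
            r = tirlib.curate_pair(
                genome, p,
                min_len=cfg.min_ir_len, min_identity=cfg.min_ir_identity,
            )
            if r.accepted:
                curated.append((r.representative, r.arm_identity, ""))
            else:
                for reason in r.reasons:
                    reject_counts[reason] = reject_counts.get(reason, 0) + 1
        fams = tirlib.deduplicate(
            curated,
            min_identity=cfg.redundancy_identity,
            min_cover=cfg.redundancy_cover,
        )
        return fams, len(curated), reject_counts

    library, n_curated, curation_rejects = stage("tirlib")(build_library)
    log.append(
        f"tirlib: {n_curated} curated -> {len(library)} families"
        f" (rejects: {sorted(curation_rejects.items())})"
    )

    # --- scan and assembly ------------------------------------------
    hits = stage("scan")(
        lambda: annotator.scan_genome(
            genome, library,
            min_len=cfg.min_tir_len,
            min_identity=cfg.min_scan_identity,
            seed_k=cfg.scan_seed_k,
        )
    )
    log.append(f"scan: {len(hits)} TIR hits")

    cargo_index = (
        annotator.make_cargo_index(cargo_lib, min_identity=cfg.min_scan_identity)
        if cargo_lib
        else None
    )
    tpase_threshold = None
    transposase_check = None
    if protein_lib:
        tpase_threshold = annotator.autonomy_threshold(protein_lib, seed=cfg.seed)
        transposase_check = (
            lambda s: annotator.best_transposase_score(s, protein_lib)
            >= tpase_threshold
        )
        log.append(f"autonomy: calibrated score threshold {tpase_threshold}")

    assembly = stage("assemble")(
        lambda: annotator.assemble_elements(
            hits, genome,
            max_span=cfg.max_span,
            min_tir_len=cfg.min_tir_len,
            max_ext_truncation=cfg.max_ext_truncation,
            tandem_window=cfg.tandem_window,
            tsd_len_range=cfg.tsd_len_range,
            tsd_max_mismatch=cfg.tsd_max_mismatch,
            cargo_index=cargo_index,
            transposase_check=transposase_check,
        )
    )
    elements = assembly.elements
    log.append(
        f"assemble: {len(elements)} elements, {len(assembly.orphans)} orphans,"
        f" {len(assembly.rejects)} rejected candidates"
    )

    # --- copy grouping, autonomy, sizes -----------------------------
    stage("group_copies")(
        lambda: annotator.group_copies(
            elements, genome,
            min_internal_fraction=cfg.copy_internal_fraction,
            min_identity=cfg.min_scan_identity,
        )
    )
    if transposase_check is not None:
        for e in elements:
            s, t = e.internal_interval()
            e.autonomous = bool(transposase_check(genome[s:t]))
    for e in elements:
        annotator.element_size(e, genome, repeat_lib)
    sizes = [e.size for e in elements]
    size_counts, size_excluded = annotator.size_histogram(
        sizes, bin_width=cfg.size_bin, max_size=cfg.size_max
    )
    family_table = annotator.family_report(elements)
    log.append(
        f"report: {family_table.shape[0] - 1 if len(family_table) else 0} families,"
        f" {size_excluded} elements above {cfg.size_max} bp"
    )

    # --- conservation and phylogeny ---------------------------------
    conservation = None
    tree = None

    def conserve():
        groups: dict[str, list[annotator.ElementRecord]] = {}
        for e in elements:
            groups.setdefault(e.copy_family or e.element_id, []).append(e)
        best = max(groups.values(), key=lambda g: (len(g), g[0].element_id))
        if len(best) < 2:
            return None
        copies = [genome[e.start : e.end] for e in best]
        return evolution.conservation_profile(
            copies, first_n=cfg.conservation_first_n,
            window=cfg.conservation_window,
        )

    conservation = stage("conserve")(conserve)

    def phylo():
        multi = [e for e in elements if e.architecture in ("type1", "type2")]
        if len(multi) < 2:
            return None
        windows = []
        for end in ("left", "right"):
            for role in ("external", "internal"):
                windows.extend(
                    evolution.extract_windows(multi, genome, end, role, 130)
                )
        aln = {w.label: w.sequence for w in windows if not w.truncated}
        if len(aln) < 4:
            return None
        return evolution.bootstrap_support(
            aln,
            n_reps=cfg.bootstrap_reps,
            seed=cfg.seed,
            consensus_threshold=cfg.consensus_threshold,
        )

    tree = stage("phylo")(phylo)

    # --- outputs ----------------------------------------------------
    def write():
        paths = {}
        fastaio.write_fasta(out_dir / "genome.fa", {"synth1": genome})
        paths["genome"] = out_dir / "genome.fa"
        fastaio.write_fasta(
            out_dir / "library.fa",
            {f.family_id: f.representative for f in library},
        )
        paths["library"] = out_dir / "library.fa"
        if repeat_lib:
            fastaio.write_fasta(out_dir / "repeats.fa", repeat_lib)
        paths.update(
            fastaio.write_outputs(
                elements, genome, out_dir / "elements", truths=truths
            )
        )
        family_table.to_csv(out_dir / "family_report.tsv", sep="\t", index=False)
        paths["family_report"] = out_dir / "family_report.tsv"
        rej = pd.DataFrame(
            [
                {"family": r.family, "start": r.start, "end": r.end,
                 "failed": ",".join(r.failed)}
                for r in assembly.rejects
            ],
            columns=["family", "start", "end", "failed"],
        )
        rej.to_csv(out_dir / "rejects.tsv", sep="\t", index=False)
        paths["rejects"] = out_dir / "rejects.tsv"
        if conservation is not None:
            pd.DataFrame(
                {"window_start": conservation.starts, "score": conservation.scores}
            ).to_csv(out_dir / "conservation.tsv", sep="\t", index=False)
            paths["conservation"] = out_dir / "conservation.tsv"
        if tree is not None:
            (out_dir / "tree.nwk").write_text(tree.newick(with_support=True))
            paths["tree"] = out_dir / "tree.nwk"
        (out_dir / "log.txt").write_text("\n".join(log) + "\n")
        paths["log"] = out_dir / "log.txt"
        return paths

    out_paths = stage("write")(write)

    return PipelineResult(
        genome=genome,
        truths=truths,
        library=library,
        elements=elements,
        orphans=assembly.orphans,
        rejects=assembly.rejects,
        family_table=family_table,
        size_counts=size_counts,
        size_excluded=size_excluded,
        conservation=conservation,
        tree=tree,
        log=log,
        out_paths=out_paths,
    )
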