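"""Shared fixtures: a small implanted world reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from mulefinder import synthgenome as sg
from mulefinder.annotator import (
    assemble_elements,
    autonomy_threshold,
    best_transposase_score,
    make_cargo_index,
    scan_genome,
)
from mulefinder.irfinder import find_inverted_repeats
from mulefinder.tirlib import curate_pair, deduplicate


class SmallWorld:
    """A 500 kb simulated genome with one family per architecture,
    carried through discovery, curation, scanning, and assembly."""

    def __init__(self):
        rng = np.random.default_rng(42)
        self.cargo = {"GENE1": sg.random_seq(rng, 300)}
        self.tpase = {"TPASE1": sg.random_protein(rng, 200)}
        self.specs = []
        for i, arch in enumerate(sg.ARCHITECTURES):
            self.specs.append(
                sg.make_element_spec(
                    rng, arch, f"FAM{i + 1}",
                    tir_len=150, internal_len=700,
                    tir_arm_identity=0.96, tsd_len=9 + (i % 3),
                    n_copies=4, copy_divergence=0.04,
                    cargo_seq=self.cargo["GENE1"] if arch in ("type1", "type5") else None,
                    transposase_protein=(
                        self.tpase["TPASE1"] if arch == "type6" else None
                    ),
                )
            )
        bg = sg.generate_background(sg.GenomeSpec(500_000, 0.4, 7))
        self.genome, self.truths = sg.implant(bg, self.specs, seed=9)
        self.pairs = find_inverted_repeats(self.genome)
        curated = [
            (r.representative, r.arm_identity, "")
            for p in self.pairs
            if (r := curate_pair(self.genome, p)).accepted
        ]
        self.library = deduplicate(curated)
        self.hits = scan_genome(self.genome, self.library)
        thr = autonomy_threshold(self.tpase, seed=0)
        self.assembly = assemble_elements(
            self.hits,
            self.genome,
            cargo_index=make_cargo_index(self.cargo),
            transposase_check=lambda s: best_transposase_score(s, self.tpase) >= thr,
        )
        self.elements = self.assembly.elements

    def truth_match(self, truth, tol=3):
        """The assembled element matching a truth record, or None."""
        for e in self.elements:
            if abs(e.start - truth.start) <= tol and abs(e.end - truth.end) <= tol:
                return e
        return None


@pytest.fixture(scope="session")
def world() -> SmallWorld:
    return SmallWorld()
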