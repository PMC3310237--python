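# Methods

## The annotation model

A MULE is modelled as a pair of long terminal inverted repeats (TIRs)
flanking an internal region, inserted into a target site whose 9–11 bp
duplication (TSD) remains as identical direct repeats immediately
outside the element. Atypical elements carry extra TIR copies and are
classified into six architectures: a tandem duplicate of the TIR
inside each external TIR (type 1 with captured gene cargo, type 2
without), a solo extra TIR in tandem with one external TIR (type 3),
or a solo TIR in the element interior (type 4 plain, type 5 with
cargo, type 6 with transposase similarity). Classification applies
five filters with these defaults, all exposed in `PipelineConfig`:

| parameter | default | meaning |
|---|---|---|
| `min_ir_len` / `min_ir_identity` | 100 bp / 80 % | de novo inverted-repeat discovery floor |
| `min_tir_len` | 50 bp | shortest hit that counts as a TIR |
| `max_span` | 20 000 bp | maximal distance between external TIRs, with no run of ≥ 10 N between them |
| `max_ext_truncation` | 15 bp | allowed loss at an external TIR terminus |
| `tandem_window` | 600 bp | tandem partner must lie closer than this to its external TIR (inner end to near end) |
| `tsd_len_range` / `tsd_max_mismatch` | 9–11 bp / 2 | flanking direct-repeat search |
| `redundancy_identity` / `redundancy_cover` | 80 % / 80 % | two TIRs are one family when this similar over this fraction of the shorter |
| `copy_internal_fraction` | 0.70 | alignable fraction of the shorter internal region for two elements to be copies |
| `conservation_first_n` / `conservation_window` | 700 bp / 5 nt | conservation profiling |
| `bootstrap_reps` / `consensus_threshold` | 1000 / 0.40 | bootstrap consensus |
| `size_bin` / `size_max` | 100 bp / 2000 bp | element-size histogram |

Percent identity is defined once for the whole package: matches
divided by alignment columns, gap columns counting as mismatches, with
the sequence pair canonicalised before alignment so the measure is
symmetric under argument order.

## Search algorithms and numerical choices

**Inverted repeats.** Under a substitution-only divergence model,
every inverted-repeat arm pair lies on one anti-diagonal of the
sequence-versus-reverse-complement comparison, so discovery seeds
exact 12-mer/reverse-complement matches and evaluates each seeded
anti-diagonal exhaustively. Candidate windows are scored +1 per match
and −2 per mismatch; the maximal-scoring run (found by a prefix-sum
Kadane scan, repeated with masking) is reported when it meets the
length and identity floors, and a failing run is searched internally
for its best qualifying sub-window. This combination stops extension
at the repeat/background boundary (random sequence matches at density
1/4, far below the 2/3 needed to sustain a penalty-2 extension), never
pads a short perfect fragment with noise columns to reach the length
floor, and still finds a diverged core inside a longer mediocre run.
Any true pair sharing at least one exact seed k-mer is found; an
exhaustive per-anti-diagonal oracle in the test suite checks both the
coverage claim and that every report re-scores above the thresholds.
The same seed-and-extend machinery (10-mer seeds) drives the library
scan, cargo search, repeat masking, and redundancy comparison.

**TSD detection** enumerates all windows of length 9–11 whose inner
edge lies within ±2 bp of the stated element boundary, comparing the
two flanks position-wise with no indels. Candidates are ranked by
fewest mismatches, then most exact abutment, then longest. (Ranking
longest-first is unusable here: for any perfect 9-mer TSD, 10/11-bp
windows at offset pairs that realign the TSD columns always qualify
within the 2-mismatch budget, so the longest candidate would never be
the true duplication. With mismatches ranked first, a clean abutting
direct repeat always wins, and among equally clean candidates the
longest is still preferred.) The annotator widens the window
asymmetrically when a hit's outer end misses representative bases —
outward by that amount (alignment trim over a mismatch-dense terminus)
and up to 6 bp inward (extension overshoot over a lucky noise run) —
and measures the effective external truncation as representative bases
absent after accounting for flank bases the TSD proves present.

**Library curation** is the strict stage: a pair enters the library
only with a near-perfect TSD (≤ 1 mismatch) within ±8 bp of its
detected termini, after which the arms are snapped to the TSD edges so
representatives are full-length. A snap that would shave off columns
still matching their inverted partners (≥ 60 % over ≥ 3 bp) is
rejected as a chance direct repeat inward of the true terminus —
without this check, trimmed representatives win the family election
with spuriously inflated identity. Redundancy clustering is greedy in
descending source-arm identity (ties: longer, then lexicographically
smaller sequence) and compares both orientations.

**Element assembly** pairs, per family, each leftmost unused hit with
the farthest admissible opposite-orientation hit; external partners
must be within `max_span` and of comparable length (shorter ≥ half the
longer), which prevents marginal ~50 bp background hits from pairing
with genuine arms kilobases away. Extra hits between the externals are
attributed to their nearer external arm; a structurally valid
candidate that fails a filter is recorded with the violated criterion
and demoted to a single-TIR-pair element (one pair of TIRs is one
element for census purposes), without retrying inner pairings that
could only form spurious smaller elements. Copy families are the
transitive closure of the pairwise copy relation.

**Autonomy** replaces a translated database search with a calibrated
score: stop-free six-frame segments (≥ 20 aa) are aligned locally
(BLOSUM62, gap open −11 / extend −1) against the supplied transposase
proteins, and the threshold is 1.5× the maximum score of 25 shuffled
2 kb null sequences — a 100-residue identical match scores several
times higher, while random internal regions fall below it.

**Phylogenetics.** Distances are Kimura two-parameter,
d = −½ ln((1 − 2P − Q)√(1 − 2Q)) over columns where both sequences
have unambiguous bases; saturation raises an explicit error (a finite
cap is substituted inside bootstrap replicates). Trees are
neighbor-joining with the smallest-(i, j) tie-break; negative branch
lengths are clamped to zero with the deficit moved to the sibling.
Bootstrap support resamples alignment columns, rebuilds the NJ tree
per replicate, and reports a greedy compatible consensus of splits at
or above the 40 % threshold. NJ on distance-based trees stands in for
likelihood tree building: it is deterministic and exactly recovers
additive matrices (tested on random binary trees of 4–12 taxa), but
its topologies are a reconstruction method choice, not a claim of
equivalence to likelihood inference.

**Conservation profiles** align every copy to a reference (the copy
with the highest mean identity to the rest), call a majority consensus
(gaps never win a column), re-project the copies against that
consensus, score each column as the fraction of copies matching it
(gap = mismatch), and average over successive 5-column windows.
Profiles are invariant to copy order.

## The simulator: what it does and does not emulate

`synthgenome` writes i.i.d. backgrounds at a chosen GC fraction and
implants elements whose TSD is duplicated from the actual insertion
site (so TSD detection is non-trivial), with per-copy independent
point mutation from a family ancestor (pairwise copy identity
≈ e^(−2·rate)), optional per-copy terminal truncations, cargo
fragments and transposase ORFs embedded in the internal region, and
nested foreign repeats recorded for the masking library. Callers
derive distinct sub-seeds for the element specifications, the
background, and the insertion sites; reusing one seed would replay the
specification RNG stream inside the background and plant literal TIR
copies there.

The simulator deliberately omits: indel mutation (divergence is
substitution-only, which is why the ungapped matcher suffices —
against real assemblies a gapped aligner would be needed), insertion
site preference and chromatin context, excision footprints, and
within-family length polymorphism beyond truncation. Passing the
recovery benchmark therefore demonstrates correctness of the
discovery/classification logic under the stated divergence model, not
performance on real genome assemblies with indels, segmental
duplications, or high-copy nested repeat nests.

## Benchmark conditions

The recovery benchmark implants 30 copies (5 single, 5 type 1, 5
type 2, 4 each of types 3–5, 3 type 6; 150 bp TIRs, 700 bp internal
regions, 96 % arm identity, 5 % copy divergence, TSD lengths cycling
9–11, one compliant 10 bp truncation) into a 2 Mb background at GC
0.42 — sizes chosen so the full chain runs in well under a minute
while every architecture and filter is exercised; the demo pipeline
uses a 300 kb genome with 22 copies for the same reason. Violator
genomes carry one element each breaking exactly one filter; the
TSD-free violator's flanks are redrawn until no window qualifies under
the annotator's search, since ~10 % of random constructions carry a
qualifying chance direct repeat.

## Known limitations

- Ungapped local matching (see above); `percent_identity` itself is
  gapped (edlib global alignment) and is used wherever two explicit
  sequences are compared.
- Identity at a window boundary equal to the threshold is decided by
  the maximal-scoring-run semantics, so a hit's terminal few bases can
  differ from the "true" terminus by 1–2 bp; TSD snapping resolves
  boundaries where it matters.
- The bootstrap consensus keeps splits at ≥ 40 % support greedily by
  frequency; below 50 % retained splits are compatible but not
  guaranteed to be jointly majority-supported.
- Chance direct repeats within the TSD search window can validate an
  element that truly lacks a TSD (~10 % of candidates under the
  default ±2 window); rates scale with the window, which is why
  curation uses the stricter ≤ 1-mismatch rule.
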