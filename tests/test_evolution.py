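"""K2P distances, NJ trees, bootstrap, conservation, motif repeats."""

import itertools
import math

import numpy as np
import pytest

from mulefinder import synthgenome as sg
from mulefinder.alignment import revcomp
from mulefinder.evolution import (
    DistanceMatrix,
    SaturationError,
    bootstrap_support,
    conservation_profile,
    find_internal_repeats,
    k2p_distance,
    k2p_matrix,
    nj_tree,
)

from .oracles import skbio_splits


class TestK2P:
    def test_identity_zero(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_single_transition(self):
        # P = 0.25, Q = 0: d = -1/2 ln(0.5)
        assert k2p_distance("AAAA", "AAAG") == pytest.approx(
            -0.5 * math.log(0.5)
        )

    def test_single_transversion(self):
        # P = 0, Q = 0.25: d = -1/2 ln(0.75 * sqrt(0.5))
        assert k2p_distance("AAAA", "AACA") == pytest.approx(
            -0.5 * math.log(0.75 * math.sqrt(0.5))
        )

    def test_closed_form_grid(self):
        # sequences constructed with exact (P, Q) counts vs the formula
        n = 120
        for p_cnt, q_cnt in itertools.product(range(0, 30, 6), range(0, 24, 6)):
            a = "A" * n
            b = "G" * p_cnt + "C" * q_cnt + "A" * (n - p_cnt - q_cnt)
            P, Q = p_cnt / n, q_cnt / n
            expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
            assert k2p_distance(a, b) == pytest.approx(expected, rel=1e-12)

    def test_saturation_signalled(self):
        with pytest.raises(SaturationError):
            k2p_distance("AAAAAA", "GGGGGG")

    def test_gap_columns_excluded(self):
        assert k2p_distance("AC-TA", "ACG-A") == 0.0

    def test_monotone_in_transitions(self):
        n = 100
        prev = -1.0
        for p_cnt in range(0, 35, 5):
            b = "G" * p_cnt + "A" * (n - p_cnt)
            d = k2p_distance("A" * n, b)
            assert d > prev
            prev = d

    def test_matrix_matches_scalar(self):
        rng = np.random.default_rng(0)
        anc = sg.random_seq(rng, 200)
        seqs = {f"t{i}": sg.diverge(anc, 0.10, rng) for i in range(4)}
        dm = k2p_matrix(seqs)
        labels = list(seqs)
        for i, j in itertools.combinations(range(4), 2):
            assert dm.data[i, j] == pytest.approx(
                k2p_distance(seqs[labels[i]], seqs[labels[j]]), abs=1e-12
            )


class TestNeighborJoining:
    def test_three_taxa_three_point_formula(self):
        dm = DistanceMatrix(["a", "b", "c"], np.array(
            [[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float
        ))
        t = nj_tree(dm)
        lengths = {c.label: c.length for c in t.children}
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_additive_matrices_recovered_exactly(self):
        # random binary trees, 4-12 taxa: NJ must recover path lengths
        rng = np.random.default_rng(1)
        for n_taxa in range(4, 13, 2):
            labels = [f"t{i}" for i in range(n_taxa)]
            # build a random additive matrix from a random tree
            dist = _random_tree_distances(labels, rng)
            D = np.zeros((n_taxa, n_taxa))
            for (i, j), v in dist.items():
                D[i, j] = D[j, i] = v
            tree = nj_tree(DistanceMatrix(labels, D))
            for (i, j), v in dist.items():
                assert tree.path_length(labels[i], labels[j]) == pytest.approx(v)

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            n = int(rng.integers(5, 9))
            M = rng.random((n, n)) * 2
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0)
            labels = [f"t{i}" for i in range(n)]
            mine = set(nj_tree(DistanceMatrix(labels, M)).splits())
            assert mine == skbio_splits(M, labels)

    def test_degenerate_two_taxa(self):
        with pytest.warns(UserWarning):
            t = nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 2.0], [2.0, 0]])))
        assert {c.label for c in t.children} == {"a", "b"}


def _random_tree_distances(labels, rng):
    """Pairwise path lengths of a random binary tree over the labels.

    Leaves are merged pairwise with random branch lengths; cross-pair
    distances are accumulated at each merge, giving an additive matrix
    realised by a binary tree.
    """
    pairs: dict[tuple[int, int], float] = {}
    clusters = [{labels.index(lab): 0.0} for lab in labels]
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        di, dj = clusters[i], clusters[j]
        li = float(rng.uniform(0.1, 2.0))
        lj = float(rng.uniform(0.1, 2.0))
        for a, va in di.items():
            for b, vb in dj.items():
                key = (a, b) if a < b else (b, a)
                pairs[key] = va + li + vb + lj
        merged = {a: v + li for a, v in di.items()}
        merged.update({b: v + lj for b, v in dj.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return pairs


class TestBootstrap:
    ALN = {
        "a1": "AAAAACCCCCGGGGG",
        "a2": "AAAAACCCCCGGGGA",
        "b1": "GGGGGTTTTTAAAAA",
        "b2": "GGGGGTTTTTAAAAC",
        "c1": "ATATATATATATATA",
    }

    def test_clean_split_full_support(self):
        t = bootstrap_support(self.ALN, n_reps=200, seed=3)
        splits = t.splits()
        assert frozenset({"b1", "b2"}) in splits
        assert splits[frozenset({"b1", "b2"})] >= 95

    def test_seeded_determinism(self):
        t1 = bootstrap_support(self.ALN, n_reps=50, seed=4)
        t2 = bootstrap_support(self.ALN, n_reps=50, seed=4)
        assert t1.newick(with_support=True) == t2.newick(with_support=True)

    def test_support_converges(self):
        a = bootstrap_support(self.ALN, n_reps=1000, seed=5).splits()
        b = bootstrap_support(self.ALN, n_reps=2000, seed=6).splits()
        for s in set(a) & set(b):
            assert abs(a[s] - b[s]) <= 5

    def test_shared_index_oracle(self):
        # replicate split counts recomputed independently from the same
        # resampled column indices
        from mulefinder.evolution import bootstrap_replicate_indices

        labels = list(self.ALN)
        n_cols = len(self.ALN[labels[0]])
        idx = bootstrap_replicate_indices(n_cols, 10, seed=7)
        counts = {}
        for rep in range(10):
            seqs = {
                lab: "".join(self.ALN[lab][c] for c in idx[rep]) for lab in labels
            }
            tree = nj_tree(k2p_matrix(seqs, saturation_cap=5.0))
            for s in tree.splits():
                counts[s] = counts.get(s, 0) + 1
        t = bootstrap_support(self.ALN, n_reps=10, seed=7, consensus_threshold=0.40)
        for s, sup in t.splits().items():
            assert sup == pytest.approx(100.0 * counts[s] / 10)


class TestConservation:
    def test_identical_copies_all_ones(self):
        prof = conservation_profile(["ACGTACGTAC"] * 3)
        assert np.allclose(prof.scores, 1.0)

    def test_hand_computed_window(self):
        copies = ["AAAAA", "AAAAA", "AAAAA", "AAAAT"]
        prof = conservation_profile(copies)
        assert prof.scores[0] == pytest.approx((4 * 1.0 + 0.75) / 5)

    def test_single_copy_rejected(self):
        with pytest.raises(ValueError):
            conservation_profile(["ACGTACGT"])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        anc = sg.random_seq(rng, 200)
        copies = [sg.diverge(anc, 0.05, rng) for _ in range(5)]
        p1 = conservation_profile(copies)
        p2 = conservation_profile(copies[::-1])
        assert np.allclose(p1.scores, p2.scores)

    def test_tir_vs_internal_contrast(self):
        # low-divergence TIRs flanking a high-divergence interior
        rng = np.random.default_rng(9)
        tir = sg.random_seq(rng, 150)
        interior = sg.random_seq(rng, 400)
        copies = []
        for _ in range(6):
            copies.append(
                sg.diverge(tir, 0.02, rng)
                + sg.diverge(interior, 0.20, rng)
                + revcomp(sg.diverge(tir, 0.02, rng))
            )
        prof = conservation_profile(copies, first_n=700)
        tir_score = prof.scores[: 150 // 5].mean()
        internal_score = prof.scores[150 // 5 : (150 + 400) // 5].mean()
        assert tir_score > internal_score + 0.1


class TestInternalRepeats:
    def test_three_copies_all_pairs(self):
        rng = np.random.default_rng(10)
        motif = sg.random_seq(rng, 20)
        tir = (
            sg.random_seq(rng, 40) + motif + sg.random_seq(rng, 30)
            + motif + sg.random_seq(rng, 25) + motif + sg.random_seq(rng, 40)
        )
        pairs = find_internal_repeats(tir)
        assert len(pairs) == 3
        starts = [40, 90, 135]
        for p in pairs:
            assert any(p.first[0] <= s < p.first[1] for s in starts)
            assert any(p.second[0] <= s < p.second[1] for s in starts)

    def test_random_sequence_no_motifs(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            assert find_internal_repeats(sg.random_seq(rng, 200)) == []

    def test_exact_tandem_duplication(self):
        rng = np.random.default_rng(12)
        unit = sg.random_seq(rng, 30)
        tir = sg.random_seq(rng, 50) + unit + unit + sg.random_seq(rng, 50)
        pairs = find_internal_repeats(tir)
        assert len(pairs) == 1
        p = pairs[0]
        # the exact 30-mer core is fully matched; the maximal extension
        # may absorb a few net-positive chance matches at the edges
        assert p.first[0] <= 50 and p.first[1] >= 80
        assert p.second[0] <= 80 and p.second[1] >= 110
        assert p.matches >= 30
        assert p.identity >= 85.0
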