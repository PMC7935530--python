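"""Marker selection, p-distances, neighbor joining (against additive-tree and
scikit-bio oracles), ecotype assignment and ANI."""

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

import oceanmg as om
from conftest import random_additive_tree, random_dna


def fam(fid, lengths):
    rng = np.random.default_rng(abs(hash(fid)) % 2**31)
    return om.MarkerFamily(
        fid, tuple(om.MarkerSeq(f"{fid}_{i}", random_dna(rng, L)) for i, L in enumerate(lengths))
    )


class TestSelectMarkerFamily:
    def test_single_family_returned(self):
        f = fam("COG0001", [900, 1000])
        assert om.select_marker_family([f]).family_id == "COG0001"

    def test_tie_breaks_lexicographically(self):
        families = [
            fam("C", [900] * 5),
            fam("A", [900] * 9),
            fam("B", [900] * 9),
        ]
        assert om.select_marker_family(families).family_id == "A"

    def test_length_filter_is_strict(self):
        f = om.select_marker_family([fam("X", [800, 801, 1200])], min_len=800)
        assert len(f.members) == 2  # the 800 bp member is dropped

    def test_matches_brute_force_survivor_count(self):
        rng = np.random.default_rng(7)
        families = [
            fam(f"F{k:02d}", rng.integers(500, 1500, size=rng.integers(1, 10)).tolist())
            for k in range(8)
        ]
        best = om.select_marker_family(families, min_len=800)
        counts = {
            f.family_id: sum(len(m.sequence) > 800 for m in f.members) for f in families
        }
        assert counts[best.family_id] == max(counts.values())

    def test_all_filtered_rejected(self):
        with pytest.raises(ValueError):
            om.select_marker_family([fam("X", [500])], min_len=800)


class TestPDistance:
    def test_identical_sequences_zero(self):
        dm = om.p_distance_matrix({"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGT"})
        assert (dm.data == 0).all()

    def test_forced_mismatch_count(self):
        dm = om.p_distance_matrix({"a": "AAAA", "b": "AATT", "c": "AAAA"})
        assert dm["a", "b"] == 0.5

    def test_gap_positions_excluded(self):
        dm = om.p_distance_matrix({"a": "AC-T", "b": "ACGT", "c": "TTTT"})
        assert dm["a", "b"] == 0.0  # 3 comparable positions, all equal

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(8)
        seqs = {f"s{i}": random_dna(rng, 200) for i in range(5)}
        dm = om.p_distance_matrix(seqs)
        ids = list(seqs)
        for i in range(5):
            for j in range(5):
                expect = np.mean([x != y for x, y in zip(seqs[ids[i]], seqs[ids[j]])])
                assert dm[ids[i], ids[j]] == pytest.approx(expect)

    def test_no_comparable_positions_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            om.p_distance_matrix({"a": "A---", "b": "-CGT", "c": "ACGT"})

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            om.p_distance_matrix({"a": "ACGT", "b": "ACG", "c": "ACGT"})


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ["a", "b", "c"])
        tree = om.nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})
        assert len(tree.children) == 3

    def test_additive_eight_leaf_recovery(self):
        rng = np.random.default_rng(9)
        _, dm = random_additive_tree(rng, 8)
        tree = om.nj_tree(dm)
        out = tree.tip_tip_distances()
        for a in dm.ids:
            for b in dm.ids:
                assert abs(out[a, b] - dm[a, b]) < 1e-9

    def test_four_point_condition_split(self):
        # additive tree ((A,B),(C,D)): NJ must return the AB|CD split
        dm = DistanceMatrix(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            ["A", "B", "C", "D"],
        )
        tree = om.nj_tree(dm)
        splits = {frozenset(t.name for t in child.tips()) for child in tree.children
                  if not child.is_tip()}
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_topology_agrees_with_skbio(self):
        rng = np.random.default_rng(10)
        _, dm = random_additive_tree(rng, 10)
        mine = om.nj_tree(dm)
        ref = skbio_nj(dm)
        assert mine.compare_rfd(ref) == 0.0

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            om.nj_tree(DistanceMatrix([[0, 1], [1, 0]], ["a", "b"]))

    def test_newick_round_trip(self):
        rng = np.random.default_rng(11)
        _, dm = random_additive_tree(rng, 6)
        tree = om.nj_tree(dm)
        back = TreeNode.read([str(tree)])
        assert tree.compare_rfd(back) == 0.0
        assert {t.name for t in back.tips()} == set(dm.ids)


def _clade_setup(seed=12, length=600):
    rng = np.random.default_rng(seed)
    ancestor = random_dna(rng, length)
    root_a = om.mutate_sequence(ancestor, 0.08, seed=seed + 1)
    root_b = om.mutate_sequence(ancestor, 0.08, seed=seed + 2)
    seqs = {
        "refA1": om.mutate_sequence(root_a, 0.02, seed=seed + 3),
        "refA2": om.mutate_sequence(root_a, 0.02, seed=seed + 4),
        "refB1": om.mutate_sequence(root_b, 0.02, seed=seed + 5),
        "refB2": om.mutate_sequence(root_b, 0.02, seed=seed + 6),
        "q1": om.mutate_sequence(root_a, 0.02, seed=seed + 7),
        "q2": om.mutate_sequence(root_a, 0.02, seed=seed + 8),
        "q3": om.mutate_sequence(root_a, 0.02, seed=seed + 9),
    }
    return seqs


class TestAssignClade:
    REFS = {"refA1": "HLII", "refA2": "HLII", "refB1": "LLI", "refB2": "LLI"}

    def test_planted_clades_recovered(self):
        seqs = _clade_setup()
        tree = om.nj_tree(om.p_distance_matrix(seqs))
        labels = om.assign_clade(["q1", "q2", "q3"], self.REFS, tree)
        assert labels == {"q1": "HLII", "q2": "HLII", "q3": "HLII"}

    def test_identical_query_gets_reference_label(self):
        seqs = _clade_setup(seed=20)
        seqs["q1"] = seqs["refB1"]
        tree = om.nj_tree(om.p_distance_matrix(seqs))
        labels = om.assign_clade(["q1"], self.REFS, tree)
        assert labels["q1"] == "LLI"

    def test_single_label_propagates(self):
        seqs = _clade_setup(seed=21)
        tree = om.nj_tree(om.p_distance_matrix(seqs))
        labels = om.assign_clade(["q1", "q2"], {"refA1": "HLI"}, tree)
        assert set(labels.values()) == {"HLI"}

    def test_no_references_rejected(self):
        seqs = _clade_setup(seed=22)
        tree = om.nj_tree(om.p_distance_matrix(seqs))
        with pytest.raises(ValueError):
            om.assign_clade(["q1"], {}, tree)


class TestGenomeANI:
    def _genome(self, rng, n_genes=5, length=400):
        return [random_dna(rng, length) for _ in range(n_genes)]

    def test_identical_genomes_100(self):
        rng = np.random.default_rng(13)
        g = self._genome(rng)
        assert om.genome_ani(g, g) == pytest.approx(100.0)

    def test_mutated_genome_tracks_divergence(self):
        rng = np.random.default_rng(14)
        a = self._genome(rng, n_genes=5, length=400)
        b = [om.mutate_sequence(g, 0.05, seed=50 + i) for i, g in enumerate(a)]
        ani = om.genome_ani(a, b)
        tol = 3 * 100 * np.sqrt(0.05 * 0.95 / (5 * 400))
        assert abs(ani - 95.0) < tol

    def test_floor_excludes_unrelated_pairs(self):
        rng = np.random.default_rng(15)
        a, b = self._genome(rng, 3), self._genome(rng, 3)
        with pytest.raises(ValueError, match="reciprocal best-hit"):
            om.genome_ani(a, b, min_identity=0.9)

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            om.genome_ani([], ["ACGT" * 50])
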