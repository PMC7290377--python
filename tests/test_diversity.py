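"""Progressive MSA, neighbor joining, and species specificity."""

import numpy as np
import pytest

from satkit import (
    DistanceMatrix,
    Sequence,
    global_align,
    make_random_sequence,
    nj_tree,
    progressive_msa,
    species_specificity,
)
from satkit.diversity import distance_matrix_from_identity
from satkit.scenarios import random_additive_matrix
from satkit.tandem import consensus_from_alignment, identity_matrix

from conftest import mutated_copies


class TestProgressiveMsa:
    def test_identical_sequences_align_without_gaps(self):
        s = make_random_sequence(80, 0.4, 1, "s")
        aligned = progressive_msa([Sequence(f"c{i}", s.residues) for i in range(4)])
        assert all(a == s.residues for a in aligned)

    def test_two_sequences_reduce_to_global_alignment(self, rng):
        a = make_random_sequence(60, 0.4, rng, "a")
        b = make_random_sequence(55, 0.4, rng, "b")
        aligned = progressive_msa([a, b])
        ref = global_align(a, b)
        assert aligned == [ref.aligned_a, ref.aligned_b]

    def test_column_consensus_recovers_the_template(self):
        template = make_random_sequence(150, 0.25, 3, "t").residues
        monomers = mutated_copies(template, 10, 0.05, 44)
        aligned = progressive_msa(monomers)
        cons = consensus_from_alignment(aligned, len(monomers))
        assert global_align(cons.residues, template).identity >= 0.98


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(["a", "b", "c"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = nj_tree(d)
        assert tree.newick == "(a:1.000000,b:1.000000,c:3.000000);"

    def test_additive_matrices_are_inverted_exactly(self):
        rng = np.random.default_rng(5)
        all_tips = None
        for _ in range(30):
            n = int(rng.integers(4, 9))
            labels, D, true_splits = random_additive_matrix(n, rng)
            tree = nj_tree(DistanceMatrix(labels, D))
            tips = frozenset(labels)
            norm = lambda ss: {min((s, tips - s), key=lambda x: sorted(x)) for s in ss}
            assert norm(set(tree.splits)) == norm(true_splits)

    def test_branch_lengths_match_path_distances_on_additive_input(self):
        import skbio

        rng = np.random.default_rng(8)
        labels, D, _ = random_additive_matrix(6, rng)
        tree = nj_tree(DistanceMatrix(labels, D))
        t = skbio.TreeNode.read([tree.newick])
        for i, a in enumerate(labels):
            for j in range(i + 1, len(labels)):
                dist = t.find(a).distance(t.find(labels[j]))
                assert dist == pytest.approx(D[i, j], abs=1e-4)

    def test_topology_agrees_with_reference_nj_implementation(self):
        import skbio
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(9)
        labels, D, _ = random_additive_matrix(7, rng)
        mine = skbio.TreeNode.read([nj_tree(DistanceMatrix(labels, D)).newick])
        ref = skbio_nj(skbio.DistanceMatrix(D, labels))
        assert mine.compare_rfd(ref) == 0.0

    def test_newick_round_trips_through_a_parser(self):
        import skbio

        rng = np.random.default_rng(10)
        labels, D, _ = random_additive_matrix(6, rng)
        tree = nj_tree(DistanceMatrix(labels, D))
        parsed = skbio.TreeNode.read([tree.newick])
        assert sorted(t.name for t in parsed.tips()) == sorted(labels)
        rewritten = str(parsed).strip()
        reparsed = skbio.TreeNode.read([rewritten])
        for a in labels[:3]:
            for b in labels[3:]:
                assert parsed.find(a).distance(parsed.find(b)) == pytest.approx(
                    reparsed.find(a).distance(reparsed.find(b)), abs=1e-6
                )

    def test_asymmetric_matrix_is_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float))

    def test_star_topology_has_zero_internal_branches(self):
        d = DistanceMatrix(
            ["a", "b", "c", "d"], np.full((4, 4), 2.0) - 2.0 * np.eye(4)
        )
        tree = nj_tree(d)
        import skbio

        t = skbio.TreeNode.read([tree.newick])
        internal = [n.length for n in t.non_tips() if n.length is not None]
        assert all(abs(x) < 1e-9 for x in internal)


class TestSpeciesSpecificity:
    def _two_species_matrix(self, between_div, seed):
        r = np.random.default_rng(seed)
        ta = make_random_sequence(120, 0.3, r, "ta").residues
        from satkit.synth import exact_substitutions

        tb = exact_substitutions(ta, round(between_div * 120), r)
        monomers = mutated_copies(ta, 4, 0.05, seed + 1, "a") + mutated_copies(
            tb, 4, 0.05, seed + 2, "b"
        )
        labels = {m.id: ("spA" if m.id.startswith("a") else "spB") for m in monomers}
        ident = identity_matrix(monomers)
        return distance_matrix_from_identity([m.id for m in monomers], ident), labels

    def test_distinct_templates_are_called_species_specific(self):
        d, labels = self._two_species_matrix(0.30, 21)
        res = species_specificity(d, labels)
        assert res.species_specific
        assert res.score_points >= 5.0
        assert res.monophyletic_species

    def test_shuffled_labels_on_one_template_are_not_specific(self):
        r = np.random.default_rng(31)
        t = make_random_sequence(120, 0.3, r, "t").residues
        monomers = mutated_copies(t, 8, 0.05, 32)
        labels = {m.id: ("spA" if i % 2 == 0 else "spB") for i, m in enumerate(monomers)}
        ident = identity_matrix(monomers)
        d = distance_matrix_from_identity([m.id for m in monomers], ident)
        res = species_specificity(d, labels)
        assert abs(res.score_points) < 5.0
        assert not res.species_specific

    def test_score_equals_direct_evaluation_of_the_rule(self):
        d, labels = self._two_species_matrix(0.25, 41)
        res = species_specificity(d, labels)
        identity = 1.0 - d.values
        within, between = [], []
        for i, a in enumerate(d.labels):
            for j in range(i + 1, len(d.labels)):
                (within if labels[a] == labels[d.labels[j]] else between).append(identity[i, j])
        expected = (np.mean(within) - np.mean(between)) * 100
        assert res.score_points == pytest.approx(expected)

    def test_singleton_species_are_excluded_and_reported(self):
        d, labels = self._two_species_matrix(0.30, 51)
        labels[d.labels[0]] = "spC"  # a species with a single monomer
        res = species_specificity(d, labels)
        assert res.excluded_species == ["spC"]
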