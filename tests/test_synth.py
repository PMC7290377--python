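"""Synthetic genome generator: determinism and truth consistency."""

import pytest

from satkit import (
    HORSpec,
    MutationModel,
    Placement,
    PlantedTruth,
    PrimerPair,
    Sequence,
    apply_mutations,
    assemble_chromosome,
    build_array,
    build_hor_monomer,
    build_te_with_satellite,
    gc_content,
    global_align,
    make_random_sequence,
    simulate_clone_set,
)
from satkit.synth import exact_substitutions


class TestRandomSequence:
    def test_gc_extremes_restrict_alphabet(self):
        assert set(make_random_sequence(200, 0.0, 1).residues) <= {"A", "T"}
        assert set(make_random_sequence(200, 1.0, 1).residues) <= {"G", "C"}

    def test_empirical_gc_tracks_target(self):
        s = make_random_sequence(10_000, 0.224, 7)
        assert abs(gc_content(s) - 0.224) < 0.02

    def test_identical_seeds_are_byte_identical(self):
        a = make_random_sequence(500, 0.4, 99)
        b = make_random_sequence(500, 0.4, 99)
        assert a.residues == b.residues


class TestMutations:
    def test_zero_rates_are_the_identity(self):
        s = make_random_sequence(300, 0.3, 2)
        assert apply_mutations(s, MutationModel(seed=5)).residues == s.residues

    def test_substitution_rate_sets_expected_identity(self):
        s = make_random_sequence(1000, 0.4, 3)
        mutated = apply_mutations(s, MutationModel(substitution_rate=0.05, seed=4))
        ident = global_align(s, mutated).identity
        assert abs(ident - 0.95) <= 0.02

    def test_rate_bounds_are_enforced(self):
        with pytest.raises(ValueError):
            MutationModel(deletion_rate=1.0)

    def test_exact_substitutions_changes_exactly_n_sites(self, rng):
        s = make_random_sequence(60, 0.3, 11).residues
        mutated = exact_substitutions(s, 9, rng)
        assert sum(1 for x, y in zip(s, mutated) if x != y) == 9


class TestHorMonomer:
    def test_two_subunit_monomer_has_exact_boundaries(self):
        spec = HORSpec([("S1", "ACGTACGTAA"), ("S2", "T" * 27)])
        mono, intervals = build_hor_monomer(spec)
        assert len(mono) == 37
        assert [(iv.start, iv.end) for _lab, iv in intervals] == [(0, 10), (10, 37)]

    def test_single_subunit_monomer_equals_subunit(self):
        spec = HORSpec([("S1", "ACGTACGT")])
        mono, _ = build_hor_monomer(spec)
        assert mono.residues == "ACGTACGT"

    def test_variant_subunits_diverge_by_the_requested_amount(self):
        seed_subunit = make_random_sequence(27, 0.2, 5).residues
        spec = HORSpec(
            [("S1-1", seed_subunit), ("S1-2", seed_subunit), ("S2", "A" * 92)],
            variant_divergence=0.40,
        )
        mono, intervals = build_hor_monomer(spec, MutationModel(seed=8))
        assert len(mono) == 146
        s11 = mono.residues[0:27]
        s12 = mono.residues[27:54]
        diffs = sum(1 for x, y in zip(s11, s12) if x != y)
        assert diffs == round(0.40 * 27)


class TestArray:
    def test_single_unmutated_copy_is_the_monomer(self):
        m = make_random_sequence(154, 0.2, 1, "m")
        arr, ivs = build_array(m, 1, MutationModel(seed=2))
        assert arr.residues == m.residues
        assert len(ivs) == 1

    def test_array_length_stays_near_expectation_with_small_indels(self):
        m = make_random_sequence(154, 0.2, 1, "m")
        model = MutationModel(
            substitution_rate=0.05, insertion_rate=0.005, deletion_rate=0.005, seed=3
        )
        arr, ivs = build_array(m, 50, model)
        assert 50 * 154 * 0.98 <= len(arr) <= 50 * 154 * 1.02
        # truth intervals tile the array without gaps
        assert ivs[0].start == 0 and ivs[-1].end == len(arr)
        assert all(a.end == b.start for a, b in zip(ivs, ivs[1:]))

    def test_copy_pairwise_identities_bounded_by_planted_rates(self, rng):
        m = make_random_sequence(100, 0.25, 4, "m")
        model = MutationModel(substitution_rate=0.05, seed=5)
        arr, ivs = build_array(m, 8, model)
        copies = [arr.residues[iv.start : iv.end] for iv in ivs]
        floor = 1 - 2 * 0.05 - 0.05
        for i in range(0, 8, 3):
            for j in range(i + 1, 8, 3):
                assert global_align(copies[i], copies[j]).identity >= floor


class TestTeElements:
    def test_tir_element_carries_tandem_units(self):
        units = [make_random_sequence(70, 0.3, 10 + i, f"u{i}") for i in range(4)]
        internal = make_random_sequence(200, 0.38, 20, "int")
        element, truth, tsd = build_te_with_satellite(
            "tir_dna", internal, units, "tandem", tsd_length=3, seed=1
        )
        monomers = truth.of_kind("monomer")
        assert len(monomers) == 4
        assert all(a.interval.end == b.interval.start for a, b in zip(monomers, monomers[1:]))
        assert tsd == 3

    def test_ltr_element_embeds_one_unit_per_ltr(self):
        unit = [make_random_sequence(146, 0.2, 3, "u")]
        internal = make_random_sequence(500, 0.38, 4, "int")
        element, truth, _ = build_te_with_satellite(
            "ltr_retro", internal, unit, "single", tsd_length=8, seed=2
        )
        assert len(truth.of_kind("monomer")) == 2
        assert len(truth.of_kind("ltr")) == 2

    def test_tandem_arrangement_requires_two_units(self):
        with pytest.raises(ValueError):
            build_te_with_satellite(
                "tir_dna",
                make_random_sequence(100, 0.4, 1),
                [make_random_sequence(70, 0.3, 2)],
                "tandem",
            )


class TestAssembleChromosome:
    def test_no_placements_gives_pure_backbone(self):
        chrom, truth = assemble_chromosome(5000, [], seed=1)
        assert len(chrom) == 5000
        assert truth.features == []

    def test_midpoint_placement_is_centered(self):
        m = make_random_sequence(100, 0.3, 1, "m")
        arr, ivs = build_array(m, 10, MutationModel(seed=2))
        from satkit.synth import TruthFeature
        from satkit.seqcore import Interval

        t = PlantedTruth([TruthFeature(Interval("a", 0, len(arr)), "array", "fam")])
        chrom, truth = assemble_chromosome(30_000, [Placement(arr, t, 15_000)], seed=3)
        iv = truth.of_kind("array")[0].interval
        mid = (iv.start + iv.end) / 2
        assert len(chrom) / 3 < mid < 2 * len(chrom) / 3

    def test_tsd_duplicates_the_insertion_site_kmer(self):
        element = make_random_sequence(400, 0.4, 5, "te")
        chrom, truth = assemble_chromosome(
            4000, [Placement(element, PlantedTruth(), 2000, "+", 3)], seed=6
        )
        tsds = truth.of_kind("tsd")
        assert len(tsds) == 2
        left, right = tsds
        seq = chrom.residues
        assert (
            seq[left.interval.start : left.interval.end]
            == seq[right.interval.start : right.interval.end]
        )
        # the 3 bp immediately flanking the element are identical
        assert right.interval.start - left.interval.end == 400

    def test_overlapping_placements_raise(self):
        e = make_random_sequence(100, 0.4, 1, "e")
        with pytest.raises(ValueError):
            assemble_chromosome(
                1000,
                [Placement(e, PlantedTruth(), 500), Placement(e, PlantedTruth(), 500)],
                seed=1,
            )

    def test_truth_sequences_align_to_their_sources(self):
        m = make_random_sequence(120, 0.25, 7, "m")
        arr, _ = build_array(m, 6, MutationModel(substitution_rate=0.05, seed=8))
        from satkit.synth import TruthFeature
        from satkit.seqcore import Interval

        ivs = [Interval("a", i * 120, (i + 1) * 120) for i in range(6)]
        t = PlantedTruth([TruthFeature(iv, "monomer", "fam") for iv in ivs])
        chrom, truth = assemble_chromosome(10_000, [Placement(arr, t, 5_000)], seed=9)
        for f in truth.of_kind("monomer"):
            piece = chrom.residues[f.interval.start : f.interval.end]
            assert global_align(piece, m.residues).identity >= 1 - 0.05 - 0.05


class TestCloneSimulation:
    def test_amplicon_ladder_lengths(self):
        m = make_random_sequence(146, 0.2, 1, "m")
        arr, _ = build_array(m, 6, MutationModel(seed=2))
        primers = PrimerPair(55, 75, 8, 28)  # first band 146 - 55 + 28 = 119
        clones = simulate_clone_set(arr, primers, 146, 3)
        assert [len(c) for c in clones] == [119, 265, 411]

    def test_single_multimer_order_gives_one_product(self):
        m = make_random_sequence(146, 0.2, 1, "m")
        arr, _ = build_array(m, 4, MutationModel(seed=2))
        clones = simulate_clone_set(arr, PrimerPair(55, 75, 8, 28), 146, 1)
        assert len(clones) == 1

    def test_secondary_forward_sites_create_off_ladder_products(self):
        # a monomer carrying the forward primer site twice
        site = "GCACGTACGTGGCCAATTGG"
        filler = make_random_sequence(60, 0.3, 3).residues
        monomer = site + filler + site + make_random_sequence(58, 0.3, 4).residues
        arr, _ = build_array(Sequence("m", monomer), 5, MutationModel(seed=5))
        primers = PrimerPair(0, 20, 140, 158, forward_seq=site)
        clones = simulate_clone_set(arr, primers, len(monomer), 2)
        lengths = sorted(len(c) for c in clones)
        ladder = {len(monomer) - 0 + 158, 2 * len(monomer) + 158}
        assert set(lengths) - ladder, "expected off-ladder products from the second site"

    def test_missing_primer_site_raises(self):
        m = make_random_sequence(146, 0.2, 1, "m")
        arr, _ = build_array(m, 4, MutationModel(seed=2))
        primers = PrimerPair(55, 75, 8, 28, forward_seq="G" * 25)
        with pytest.raises(ValueError):
            simulate_clone_set(arr, primers, 146, 2)
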