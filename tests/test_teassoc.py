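"""Genome similarity scanning, hit clustering, TSD detection, association calls."""

import numpy as np
import pytest

from satkit import (
    MutationModel,
    Placement,
    PlantedTruth,
    Sequence,
    assemble_chromosome,
    classify_association,
    cluster_hits,
    detect_tsd,
    global_align,
    make_random_sequence,
    reverse_complement,
    scan_similarity,
)
from satkit.seqcore import Interval
from satkit.synth import TruthFeature, _mutate_residues

from conftest import mutated_copies


def _plant(units, positions, backbone_len=6000, seed=3):
    placements = [
        Placement(u, PlantedTruth([TruthFeature(Interval("u", 0, len(u)), "monomer", "fam")]), p)
        for u, p in zip(units, positions)
    ]
    return assemble_chromosome(backbone_len, placements, seed=seed)


class TestScanSimilarity:
    def test_exact_copy_is_found_with_full_identity_and_coverage(self):
        q = make_random_sequence(154, 0.25, 1, "q")
        chrom, truth = _plant([q], [3000])
        hits = scan_similarity(q, chrom)
        assert len(hits) == 1
        h = hits[0]
        assert h.identity == 1.0 and h.coverage == 1.0
        t = truth.of_kind("monomer")[0].interval
        assert h.interval.start == t.start and h.interval.end == t.end

    def test_minus_strand_copy_is_found_with_correct_interval(self):
        q = make_random_sequence(154, 0.25, 2, "q")
        rc = Sequence("rc", reverse_complement(q.residues))
        chrom, truth = _plant([rc], [3000])
        hits = scan_similarity(q, chrom)
        assert len(hits) == 1
        assert hits[0].interval.strand == "-"
        t = truth.of_kind("monomer")[0].interval
        assert hits[0].interval.start == t.start and hits[0].interval.end == t.end

    def test_identity_floor_separates_planted_divergence_levels(self):
        r = np.random.default_rng(7)
        q = make_random_sequence(154, 0.25, 4, "q").residues
        model = lambda rate: MutationModel(substitution_rate=rate)
        copies = {
            rate: Sequence(f"c{rate}", _mutate_residues(q, model(rate), r))
            for rate in (0.10, 0.30)
        }
        chrom, truth = _plant(list(copies.values()), [1500, 4000])
        hits = scan_similarity(Sequence("q", q), chrom, min_identity=0.80, min_coverage=0.80)
        # alignment identity ~0.90 at 10% divergence, ~0.70 at 30%
        assert len(hits) == 1
        t10 = truth.of_kind("monomer")[0].interval
        assert hits[0].interval.overlap_len(t10) > 100

    def test_recall_on_planted_copies_across_lengths(self):
        for length in (49, 154, 238):
            r = np.random.default_rng(length)
            q = make_random_sequence(length, 0.3, length, "q").residues
            copies = [
                Sequence(f"c{i}", _mutate_residues(q, MutationModel(substitution_rate=0.10), r))
                for i in range(5)
            ]
            chrom, truth = _plant(copies, [1000, 2000, 3000, 4000, 5000], 7000, seed=length)
            hits = scan_similarity(Sequence("q", q), chrom, 0.80, 0.80)
            for t in truth.of_kind("monomer"):
                assert any(h.interval.overlap_len(t.interval) >= 0.5 * len(t.interval) for h in hits)


class TestClusterHits:
    def test_copies_of_one_template_form_one_cluster(self):
        q = make_random_sequence(120, 0.3, 5, "q")
        copies = [Sequence(f"c{i}", s.residues) for i, s in enumerate(mutated_copies(q.residues, 5, 0.05, 6))]
        chrom, _ = _plant(copies, [800, 1800, 2800, 3800, 4800])
        hits = scan_similarity(q, chrom, 0.8, 0.8)
        clusters = cluster_hits(hits, chrom)
        assert len(clusters) == 1
        cons = clusters[0].consensus
        assert global_align(cons, q.residues).identity >= 0.95

    def test_distinct_templates_form_distinct_clusters(self):
        r = np.random.default_rng(8)
        qa = make_random_sequence(120, 0.3, 9, "qa").residues
        qb = make_random_sequence(120, 0.3, 10, "qb").residues
        copies = [Sequence("a1", qa), Sequence("a2", qa), Sequence("b1", qb), Sequence("b2", qb)]
        chrom, _ = _plant(copies, [800, 1800, 2800, 3800])
        hits = []
        for q in (qa, qb):
            hits.extend(scan_similarity(Sequence("q", q), chrom, 0.9, 0.9))
        clusters = cluster_hits(hits, chrom)
        assert len(clusters) == 2

    def test_single_linkage_chains_through_an_intermediate(self):
        # a-b and b-c each link (>= 75% identity); a-c alone would not
        r = np.random.default_rng(11)
        a = make_random_sequence(120, 0.5, r).residues
        b = _mutate_residues(a, MutationModel(substitution_rate=0.16), r)
        c = _mutate_residues(b, MutationModel(substitution_rate=0.16), r)
        from satkit.seqcore import local_align

        assert local_align(a, b).identity >= 0.75
        assert local_align(b, c).identity >= 0.75
        assert local_align(a, c).identity < 0.75
        chrom, _ = _plant([Sequence("a", a), Sequence("b", b), Sequence("c", c)], [800, 1800, 2800])
        hits = [
            scan_similarity(Sequence("q", s), chrom, 0.95, 0.95)[0] for s in (a, b, c)
        ]
        clusters = cluster_hits(hits, chrom)
        assert len(clusters) == 1


class TestDetectTsd:
    def test_planted_trinucleotide_tsd_is_recovered(self):
        element = make_random_sequence(400, 0.4, 1, "te")
        backbone = make_random_sequence(3000, 0.38, 2, "chr").residues
        pos = backbone.find("TAA", 1000)
        chrom, truth = assemble_chromosome(
            3000, [Placement(element, PlantedTruth(), pos, "+", 3)], seed=3, backbone=backbone
        )
        left, right = (f.interval for f in truth.of_kind("tsd"))
        te = Interval("chr", left.end, right.start)
        assert detect_tsd(chrom, te) == (3, "TAA")

    @pytest.mark.parametrize("tsd_len", [3, 8, 9])
    def test_planted_tsd_lengths_recovered(self, tsd_len):
        element = make_random_sequence(400, 0.4, tsd_len, "te")
        chrom, truth = assemble_chromosome(
            3000, [Placement(element, PlantedTruth(), 1500, "+", tsd_len)], seed=tsd_len + 7
        )
        left, right = (f.interval for f in truth.of_kind("tsd"))
        te = Interval("chr", left.end, right.start)
        res = detect_tsd(chrom, te)
        assert res is not None and res[0] == tsd_len
        assert res[1] == chrom.residues[left.start : left.end]

    def test_random_flanks_usually_yield_nothing(self):
        none_count = 0
        for seed in range(30):
            chrom = make_random_sequence(500, 0.38, seed, "chr")
            if detect_tsd(chrom, Interval("chr", 200, 300)) is None:
                none_count += 1
        # anchored >= 2 bp match has false-positive probability ~1/16
        assert none_count >= 24

    def test_contig_edge_returns_none_with_warning(self):
        chrom = make_random_sequence(100, 0.38, 1, "chr")
        with pytest.warns(UserWarning, match="contig edge"):
            assert detect_tsd(chrom, Interval("chr", 2, 60)) is None


class TestClassifyAssociation:
    def _hits(self, spans, strand="+"):
        return [
            Interval("chr", s, e, strand)
            for s, e in spans
        ]

    def _as_hits(self, intervals):
        from satkit.teassoc import SimilarityHit

        return [SimilarityHit(iv, 0.9, 1.0, "q") for iv in intervals]

    def test_four_adjacent_units_inside_a_te_are_tandem(self):
        hits = self._as_hits(self._hits([(100, 170), (172, 242), (244, 314), (316, 386)]))
        call = classify_association(hits, Interval("chr", 50, 450))
        assert call.arrangement == "tandem_in_te"

    def test_single_unit_inside_an_element_is_dispersed(self):
        hits = self._as_hits(self._hits([(100, 170)]))
        call = classify_association(hits, Interval("chr", 50, 450))
        assert call.arrangement == "dispersed_in_te"

    def test_two_distant_units_inside_an_element_are_dispersed(self):
        hits = self._as_hits(self._hits([(100, 170), (1000, 1070)]))
        call = classify_association(hits, Interval("chr", 50, 1450))
        assert call.arrangement == "dispersed_in_te"

    def test_array_without_element_is_standalone(self):
        spans = [(100 + i * 72, 170 + i * 72) for i in range(10)]
        call = classify_association(self._as_hits(self._hits(spans)), None)
        assert call.arrangement == "standalone_array"

    def test_isolated_hit_without_element_is_no_association(self):
        call = classify_association(self._as_hits(self._hits([(100, 170)])), None)
        assert call.arrangement == "none"
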