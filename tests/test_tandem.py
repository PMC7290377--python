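"""Dotplots, periodicity, monomer extraction and consensus building."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from satkit import (
    MutationModel,
    Sequence,
    build_array,
    build_consensus,
    estimate_period,
    extract_monomers,
    global_align,
    identity_matrix,
    make_random_sequence,
    reverse_complement,
    windowed_dotplot,
    wordmatch_segments,
)
from satkit.scenarios import brute_windowed_dotplot, brute_wordmatch
from satkit.synth import exact_substitutions

from conftest import mutated_copies


class TestWordmatch:
    def test_self_comparison_contains_the_full_main_diagonal(self, rng):
        s = make_random_sequence(60, 0.4, rng)
        segs = wordmatch_segments(s, s, 10, 0)
        main = [g for g in segs if g.a_start == g.b_start == 0 and g.a_end == 60]
        assert len(main) == 1 and main[0].mismatches == 0

    def test_reverse_complement_gives_a_full_minus_segment(self, rng):
        s = make_random_sequence(50, 0.4, rng)
        rc = Sequence("rc", reverse_complement(s.residues))
        segs = wordmatch_segments(s, rc, 10, 0, both_strands=True)
        minus = [g for g in segs if g.strand == "-"]
        assert any(g.a_start == 0 and g.a_end == 50 and g.b_start == 0 for g in minus)

    def test_word_size_longer_than_input_yields_nothing(self):
        assert wordmatch_segments("ACGTACGT", "ACGTACGT", 10, 1) == []

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_agreement_with_exhaustive_window_enumeration(self, seed):
        r = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        a = "".join(r.choice(bases, int(r.integers(15, 80))))
        b = "".join(r.choice(bases, int(r.integers(15, 80))))
        segs = wordmatch_segments(a, b, 10, 2, both_strands=True)
        mine = sorted((g.a_start, g.a_end, g.b_start, g.b_end, g.strand, g.mismatches) for g in segs)
        assert mine == brute_wordmatch(a, b, 10, 2, both_strands=True)


class TestWindowedDotplot:
    def test_identical_sequences_fill_the_main_diagonal(self, rng):
        s = make_random_sequence(40, 0.4, rng)
        M = windowed_dotplot(s, s, 14, 27)
        pts = set(zip(M.row.tolist(), M.col.tolist()))
        assert all((i, i) in pts for i in range(40))

    def test_score_bound_keeps_weak_windows_unset(self):
        # max score with <= 4 matches is 5*4 - 4*10 = -20 < 27
        a = "A" * 20
        b = "C" * 16 + "AAAA"
        M = windowed_dotplot(a, b, 14, 27)
        assert M.nnz == 0

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_agreement_with_exhaustive_window_scoring(self, seed):
        r = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        a = "".join(r.choice(bases, int(r.integers(14, 60))))
        b = "".join(r.choice(bases, int(r.integers(14, 60))))
        M = windowed_dotplot(a, b, 14, 27)
        assert set(zip(M.row.tolist(), M.col.tolist())) == brute_windowed_dotplot(a, b, 14, 27)


class TestPeriodEstimate:
    def test_perfect_tetramer_repeat(self):
        est = estimate_period(Sequence("x", "ACGT" * 25))
        assert est.period == 4 and est.support == 1.0

    def test_planted_monomer_length_is_recovered(self):
        template = make_random_sequence(37, 0.2, 5, "m")
        arr, _ = build_array(template, 12, MutationModel(substitution_rate=0.05, seed=6))
        est = estimate_period(arr, min_period=10)
        assert est is not None and est.period == 37

    @pytest.mark.parametrize("length", [36, 70, 101, 154, 240])
    def test_recovery_across_the_monomer_length_range(self, length):
        template = make_random_sequence(length, 0.25, length, "m")
        arr, _ = build_array(template, 10, MutationModel(substitution_rate=0.08, seed=length))
        est = estimate_period(arr, min_period=10, max_period=300)
        assert est is not None and est.period == length

    def test_random_sequence_has_no_period(self, rng):
        assert estimate_period(make_random_sequence(1000, 0.4, rng)) is None


class TestExtractMonomers:
    def test_perfect_array_cuts_into_identical_monomers(self):
        template = make_random_sequence(100, 0.3, 1, "m")
        arr, _ = build_array(template, 5, MutationModel(seed=2))
        monomers, partials, ivs = extract_monomers(arr, template)
        assert len(monomers) == 5 and not partials
        assert all(m.residues == template.residues for m in monomers)

    def test_multimeric_clone_yields_monomers_plus_partial(self):
        template = make_random_sequence(100, 0.3, 3, "m")
        clone = Sequence("clone", template.residues * 2 + template.residues[:40])
        monomers, partials, _ = extract_monomers(clone, template)
        assert len(monomers) == 2 and len(partials) == 1
        assert len(partials[0]) < 50

    def test_period_mode_respects_phase(self):
        template = make_random_sequence(50, 0.3, 4, "m")
        from satkit.tandem import PeriodEstimate

        seq = Sequence("s", "TTT" + template.residues * 3)
        mono, partials, ivs = extract_monomers(seq, PeriodEstimate(50, 1.0, 3))
        assert len(mono) == 3
        assert ivs[0].start == 3
        assert len(partials) == 1  # leading 3 bp fragment

    def test_unrelated_reference_raises(self, rng):
        seq = make_random_sequence(300, 0.1, rng, "s")
        ref = make_random_sequence(100, 0.9, rng, "ref")
        with pytest.raises(ValueError):
            extract_monomers(seq, ref, min_identity=0.8)

    def test_boundaries_recovered_within_two_bp_at_planted_divergence(self):
        template = make_random_sequence(120, 0.25, 9, "m")
        arr, truth = build_array(template, 20, MutationModel(substitution_rate=0.05, seed=10))
        monomers, _, ivs = extract_monomers(arr, template)
        matched = 0
        for iv in ivs:
            if any(abs(iv.start - t.start) <= 2 and abs(iv.end - t.end) <= 2 for t in truth):
                matched += 1
        assert matched >= 0.95 * len(truth)


class TestConsensus:
    def test_identical_monomers_reproduce_themselves(self):
        m = make_random_sequence(80, 0.3, 1, "m")
        prof = build_consensus([Sequence(f"c{i}", m.residues) for i in range(5)])
        assert prof.residues == m.residues
        assert all(s == 1.0 for s in prof.column_support)

    def test_majority_vote_with_tie_break(self):
        seqs = [Sequence("a", "AACGT"), Sequence("b", "AACGT"), Sequence("c", "CACGT")]
        prof = build_consensus(seqs)
        assert prof.residues == "AACGT"
        assert prof.column_support[0] == pytest.approx(2 / 3)

    def test_consensus_recovers_template_from_noisy_copies(self):
        template = make_random_sequence(150, 0.25, 2, "m").residues
        prof = build_consensus(mutated_copies(template, 20, 0.05, 33))
        aln = global_align(prof.residues, template)
        assert aln.identity >= (len(template) - 1) / len(template)


class TestIdentityMatrix:
    def test_identical_pair_scores_one(self):
        m = make_random_sequence(60, 0.3, 1, "m")
        mat = identity_matrix([m, Sequence("b", m.residues)])
        assert mat[0, 1] == 1.0

    def test_masking_everything_raises(self):
        m1 = make_random_sequence(30, 0.3, 1, "a")
        m2 = Sequence("b", m1.residues)
        with pytest.raises(ValueError):
            identity_matrix([m1, m2], mask=[(0, 30)])

    def test_masking_a_conserved_region_lowers_identity(self, rng):
        conserved = make_random_sequence(20, 0.5, rng).residues
        v1 = make_random_sequence(20, 0.2, rng).residues
        v2 = exact_substitutions(v1, 10, rng)
        m1 = Sequence("m1", conserved + v1)
        m2 = Sequence("m2", conserved + v2)
        full = identity_matrix([m1, m2])[0, 1]
        masked = identity_matrix([m1, m2], mask=[(0, 20)])[0, 1]
        assert masked < full


class TestHorDotplotStructure:
    def test_hor_array_shows_subunit_and_monomer_lags(self):
        # monomer = S1 + echo(S1) + tail: the self-dotplot of the array must
        # show off-diagonals at the subunit lag and at the monomer period
        r = np.random.default_rng(77)
        s1 = make_random_sequence(20, 0.25, r).residues
        echo = exact_substitutions(s1, 2, r)
        tail = make_random_sequence(30, 0.25, r).residues
        monomer = s1 + echo + tail
        arr = Sequence("arr", monomer * 4)
        segs = wordmatch_segments(arr, arr, 8, 1)
        lags = {g.b_start - g.a_start for g in segs}
        assert 20 in lags or -20 in lags  # subunit lag
        assert 70 in lags or -70 in lags  # monomer period
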