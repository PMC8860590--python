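"""Locus annotation: flanks, promoter, tandem repeats, terminator, ORFs,
classification, and end-to-end recovery of synthetic loci."""

import math

import numpy as np
import pytest

from conftest import random_dna
from oracles import best_repeat_score, promoter_scan, six_frame_orfs, terminator_scan
from ta3scan.annotate import (
    OrfHit,
    RepeatFinderParams,
    annotate_ta_locus,
    classify_locus,
    extract_flanks,
    find_orf,
    find_tandem_repeats,
    find_terminator,
    revcomp,
    scan_promoter,
)
from ta3scan.synthetic import (
    DEFAULT_REPEAT_UNIT_DNA,
    LocusSpec,
    make_repeat_array_fixture,
    make_ta_locus,
)


class TestExtractFlanks:
    def test_boundary_clip_at_origin(self):
        genome = "ATG" + "A" * 97
        region = extract_flanks(genome, (0, 3), up=1000, down=10)
        assert region.genome_start == 0
        assert region.sequence == genome[:13]

    def test_mid_genome_length(self):
        genome = "A" * 5000
        region = extract_flanks(genome, (2000, 2300), up=1000, down=1000)
        assert len(region.sequence) == 1000 + 300 + 1000

    def test_round_trip_coordinates(self):
        rng = np.random.default_rng(0)
        genome = random_dna(rng, 3000)
        region = extract_flanks(genome, (1200, 1500))
        s, e = region.to_region(1200), region.to_region(1500)
        assert region.sequence[s:e] == genome[1200:1500]

    def test_interval_outside_genome_rejected(self):
        with pytest.raises(ValueError):
            extract_flanks("ACGT" * 10, (30, 50))


class TestPromoterScan:
    def test_consensus_boxes_score_twelve(self):
        seq = "GGGG" + "TTGACA" + "C" * 17 + "TATAAT" + "GGGG"
        hits = scan_promoter(seq)
        top = hits[0]
        assert top.score == 12
        assert top.spacer == 17
        assert top.mismatches == (0, 0)
        assert top.minus35 == (4, 10)
        assert top.minus10 == (27, 33)

    def test_polya_yields_nothing(self):
        assert scan_promoter("A" * 80) == []

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        # AT-rich alphabet so mismatch-2 boxes actually occur
        seq = "".join("AT GACT"[i] for i in rng.integers(7, size=80)).replace(" ", "")[:80]
        seq = (seq + "A" * 80)[:80]
        hits = scan_promoter(seq)
        mine = sorted((h.minus35, h.minus10, h.spacer, h.score) for h in hits)
        assert mine == promoter_scan(seq)


class TestTandemRepeats:
    def test_perfect_array_scores_two_per_base(self):
        region = (DEFAULT_REPEAT_UNIT_DNA * 5)[:165]
        arrays = find_tandem_repeats(region)
        assert len(arrays) == 1
        a = arrays[0]
        assert (a.period, a.copies, a.score) == (36, 4.6, 330)
        assert a.consensus == DEFAULT_REPEAT_UNIT_DNA

    def test_reporting_threshold_is_inclusive_fifty(self):
        unit = "ACGTTGCAGGTC"
        below, _ = make_repeat_array_fixture(unit, 2.0, flank=40, seed=4)  # 24 nt -> 48
        assert not any(a.period == 12 for a in find_tandem_repeats(below))
        at, _ = make_repeat_array_fixture(unit, 2.1, flank=40, seed=4)  # 25 nt -> 50
        hits = find_tandem_repeats(at)
        assert any(a.period == 12 and a.score == 50 and a.copies == 2.1 for a in hits)

    @pytest.mark.parametrize("seed", range(10))
    def test_no_arrays_in_shuffled_sequence(self, seed):
        rng = np.random.default_rng(seed)
        assert find_tandem_repeats(random_dna(rng, 200)) == []

    @pytest.mark.parametrize("seed", range(12))
    def test_score_matches_bruteforce_on_short_sequences(self, seed):
        """Wraparound-DP score equals the exhaustive best-window score.

        At most one substitution is planted so that an exact 7-mer
        recurrence survives for the candidate-proposal stage; the scoring
        itself is then checked against full enumeration.
        """
        rng = np.random.default_rng(200 + seed)
        unit = random_dna(rng, int(rng.integers(10, 13)))
        n_copies = int(rng.integers(3, 5))
        region = list(unit * n_copies)[:60]
        if rng.random() < 0.7:
            pos = int(rng.integers(len(region)))
            region[pos] = "ACGT"[rng.integers(4)]
        seq = "".join(region)
        arrays = find_tandem_repeats(seq, min_copies=2.0)
        expected = best_repeat_score(seq, min_period=3, max_period=len(seq) // 2)
        if expected >= 50:
            assert arrays, f"oracle found score {expected}, detector found none"
            assert arrays[0].score == expected
        else:
            assert arrays == []

    def test_reported_arrays_never_below_min_score(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            seq = random_dna(rng, 80) + (DEFAULT_REPEAT_UNIT_DNA * 3) + random_dna(rng, 80)
            for a in find_tandem_repeats(seq):
                assert a.score >= 50

    def test_params_validation(self):
        with pytest.raises(ValueError):
            RepeatFinderParams(match=0)
        with pytest.raises(ValueError):
            find_tandem_repeats("ACGT")


class TestTerminator:
    def test_designed_hairpin(self):
        seq = "GCGCG" + "AAAA" + "CGCGC" + "TTTTT"
        hits = find_terminator(seq)
        assert len(hits) == 1
        h = hits[0]
        assert (h.stem, h.loop, h.u_tract) == (5, 4, 5)
        assert h.hairpin == (0, 14)
        assert h.score == 15

    def test_polypurine_yields_nothing(self):
        assert find_terminator("AGAGAGAGAGAGAGAGAG") == []

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 60)
        hits = find_terminator(seq)
        mine = sorted((h.hairpin, h.stem, h.loop, h.u_tract, h.score) for h in hits)
        assert mine == terminator_scan(seq)


class TestOrf:
    def test_single_orf_length_includes_stop(self):
        rng = np.random.default_rng(1)
        codons = []
        while len(codons) < 59:
            c = random_dna(rng, 3)
            if c not in {"TAA", "TAG", "TGA", "ATG", "GTG"}:
                codons.append(c)
        seq = "CC" + "ATG" + "".join(codons) + "TAA" + "CC"
        hits = find_orf(seq, strand="+", min_len=30)
        assert len(hits) == 1
        assert hits[0].length == 61
        assert hits[0].interval == (2, 2 + 61 * 3)

    def test_no_start_codon_yields_nothing(self):
        assert find_orf("CCCTTTCCCTTT" * 30, strand="both") == []

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_six_frame_bruteforce(self, seed):
        rng = np.random.default_rng(50 + seed)
        seq = random_dna(rng, 300)
        hits = find_orf(seq, strand="both", min_len=10)
        mine = sorted(set((h.interval[0], h.interval[1], h.strand) for h in hits))
        assert mine == six_frame_orfs(seq, min_len=10)


class TestClassify:
    def test_synthetic_locus_is_functional_and_matches_ground_truth(self):
        seq, truth = make_ta_locus(LocusSpec(seed=21))
        a = annotate_ta_locus(seq)
        assert a.is_functional_candidate
        assert a.promoter.minus35 == truth.elements["promoter_-35"]
        assert a.promoter.minus10 == truth.elements["promoter_-10"]
        assert a.repeats.interval == truth.elements["repeats"]
        assert a.terminator.hairpin == truth.elements["terminator"]
        assert a.orf.interval == truth.elements["orf"]

    def test_missing_terminator_reported(self):
        seq, _ = make_ta_locus(LocusSpec(seed=21))
        a = annotate_ta_locus(seq)
        verdict = classify_locus(a.promoter, a.repeats, None, a.orf)
        assert not verdict.is_functional_candidate
        assert any("missing terminator" in f for f in verdict.failures)

    def test_order_violation_reported(self):
        seq, _ = make_ta_locus(LocusSpec(seed=21))
        a = annotate_ta_locus(seq)
        # shift the repeat array upstream of the -10 box
        import dataclasses

        bad = dataclasses.replace(a.repeats, interval=(0, a.repeats.interval[1] - a.repeats.interval[0]))
        verdict = classify_locus(a.promoter, bad, a.terminator, a.orf)
        assert any("(ii)" in f for f in verdict.failures)

    def test_minus_strand_elements_rejected(self):
        orf = OrfHit(interval=(10, 100), strand="-", start_codon="ATG", length=30)
        with pytest.raises(ValueError):
            classify_locus(None, None, None, orf)


class TestEndToEnd:
    @pytest.mark.parametrize("copies", [3.0, 3.8, 4.0, 4.6, 5.6])
    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_recovery_across_copy_numbers(self, copies, seed):
        seq, truth = make_ta_locus(LocusSpec(copies=copies, seed=seed))
        a = annotate_ta_locus(seq)
        assert a.is_functional_candidate
        assert a.repeats.period == truth.extras["period"]
        assert abs(a.repeats.copies - truth.extras["copies"]) <= 0.1

    def test_single_copy_region_equals_unit(self):
        # one copy carries no periodicity signal for any detector; the
        # generator-level contract is that the region equals the unit exactly
        seq, truth = make_ta_locus(LocusSpec(copies=1.0, seed=5, flank_length=300))
        s, e = truth.elements["repeats"]
        assert seq[s:e] == DEFAULT_REPEAT_UNIT_DNA

    def test_reverse_complement_equivariance(self):
        seq, _ = make_ta_locus(LocusSpec(seed=13))
        fwd = annotate_ta_locus(seq)
        rev = annotate_ta_locus(revcomp(seq))
        assert rev.strand == "-"
        assert rev.verdict == fwd.verdict
        assert rev.repeats.interval == fwd.repeats.interval
        assert rev.promoter.minus35 == fwd.promoter.minus35
        assert rev.terminator.hairpin == fwd.terminator.hairpin
        assert rev.orf.interval == fwd.orf.interval
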