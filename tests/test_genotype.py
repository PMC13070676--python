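"""Window construction, read genotyping, fragment aggregation, VAF."""

import pytest

from fragtyper.genotype import (
    CigarEvidence,
    FragmentCall,
    FragmentStatus,
    ReadCall,
    ReadStatus,
    Resolution,
    build_window,
    cigar_indel_scan,
    genotype_fragment,
    genotype_read,
    locus_vaf,
    read_window_sequence,
)
from fragtyper.variants import (
    Mutation,
    MutationType,
    RawVariant,
    normalize,
    resolve_alleles,
)

from conftest import make_read

SNV = Mutation("chr1", 100, "A", "T", MutationType.SNV, normalized=True)


def snv_window(reference):
    return build_window(SNV, reference)


class TestBuildWindow:
    def test_snv_core_and_extended(self, reference):
        w = snv_window(reference)
        assert (w.w_start, w.w_end) == (100, 100)
        assert w.extended_interval == (99, 101)
        assert w.ref_hap == "A" and w.alt_hap == "T"

    def test_deletion_window_spans_homopolymer_run(self, reference):
        # chr1 601..606 = CAAAAG; deleting one A must extend through the
        # whole run to the terminating G
        m = normalize(Mutation("chr1", 601, "CA", "C", MutationType.DEL),
                      reference)
        w = build_window(m, reference)
        assert (w.w_start, w.w_end) == (601, 606)
        assert w.ref_hap == "CAAAAG" and w.alt_hap == "CAAAG"
        # oracle: this is the smallest right edge at which no observation
        # can match the truncated wild-type and mutated haplotypes at once
        for edge in range(m.pos + 1, w.w_end):
            trunc = edge - m.pos + 1
            assert w.ref_hap[:trunc - 1] == w.alt_hap[:trunc - 1] or \
                w.ref_hap[:trunc] != w.alt_hap[:trunc]
        assert w.ref_hap != w.alt_hap

    def test_insertion_window_spans_repeat_copies(self, reference):
        # chr1 500..505 = ATGTGC; inserting TG after 500 extends through
        # both TG copies plus the terminating C
        m = Mutation("chr1", 500, "A", "ATG", MutationType.INS, normalized=True)
        w = build_window(m, reference)
        assert (w.w_start, w.w_end) == (500, 505)
        assert w.ref_hap == "ATGTGC"
        assert w.alt_hap == "ATG" + "TGTGC"


class TestReadWindowSequence:
    def test_spanning_read_observes_core_base(self, reference):
        w = snv_window(reference)
        r = make_read(pos=80, cigar="40M", reference=reference)
        obs = read_window_sequence(r, w)
        assert obs.observed == "A"  # reference base at 100
        assert not obs.truncated_left and not obs.truncated_right

    def test_insertion_inside_window_appears(self, reference):
        m = Mutation("chr1", 500, "A", "ATG", MutationType.INS, normalized=True)
        w = build_window(m, reference)
        r = make_read(pos=480, cigar="21M2I20M", reference=reference,
                      inserted="TG")
        obs = read_window_sequence(r, w)
        assert obs.observed == w.alt_hap

    def test_read_ending_mid_window_truncated(self, reference):
        m = normalize(Mutation("chr1", 601, "CA", "C", MutationType.DEL),
                      reference)
        w = build_window(m, reference)
        r = make_read(pos=580, cigar="24M", reference=reference)  # ends at 603
        obs = read_window_sequence(r, w)
        assert obs.truncated_right and not obs.truncated_left
        assert obs.observed == reference.fetch("chr1", 601, 603)

    def test_no_overlap_marks_no_coverage(self, reference):
        w = snv_window(reference)
        r = make_read(pos=500, cigar="40M", reference=reference)
        assert not read_window_sequence(r, w).covered


class TestCigarIndelScan:
    DEL15 = None  # built per test from the reference

    def _del15(self, reference):
        raw = RawVariant("chr1", 900, reference.fetch("chr1", 900, 915),
                         reference.fetch("chr1", 900, 900))
        return normalize(resolve_alleles(raw, reference), reference)

    def test_expected_deletion_at_anchor(self, reference):
        m = self._del15(reference)
        r = make_read(pos=m.pos - 30, cigar=f"31M15D30M", reference=reference)
        ev, other = cigar_indel_scan(r, m, reference)
        assert ev is CigarEvidence.EXPECTED_INDEL and not other

    def test_wrong_type_in_window_is_other(self, reference):
        m = self._del15(reference)
        r = make_read(pos=m.pos - 30, cigar="35M1I25M", reference=reference,
                      inserted="G")
        ev, other = cigar_indel_scan(r, m, reference)
        assert ev is CigarEvidence.OTHER_INDEL and other

    def test_match_only_cigar_is_none(self, reference):
        m = self._del15(reference)
        r = make_read(pos=m.pos - 30, cigar="61M", reference=reference)
        assert cigar_indel_scan(r, m, reference)[0] is CigarEvidence.NONE

    def test_right_shifted_encoding_left_aligns_to_match(self, reference):
        # 1bp deletion in the chr1 A-run (302..305); a CIGAR encoding the
        # deletion 2 bases to the right denotes the same variant
        m = normalize(Mutation("chr1", 301, "CA", "C", MutationType.DEL),
                      reference)
        r = make_read(pos=284, cigar="20M1D20M", reference=reference)
        assert cigar_indel_scan(r, m, reference)[0] is \
            CigarEvidence.EXPECTED_INDEL


class TestGenotypeRead:
    def _read_with_base(self, reference, base, pos=80, cigar="40M"):
        seq = list(reference.fetch("chr1", 80, 119))
        seq[100 - 80] = base
        return make_read(pos=pos, cigar=cigar, seq="".join(seq))

    def test_snv_statuses(self, reference):
        w = snv_window(reference)
        for base, status in (("T", ReadStatus.MUT), ("A", ReadStatus.WT),
                             ("G", ReadStatus.OTH)):
            call = genotype_read(self._read_with_base(reference, base), SNV, w)
            assert call.status is status
            assert "possible_larger_event" not in call.flags

    def test_flank_mismatch_flags_larger_event(self, reference):
        w = snv_window(reference)
        seq = list(reference.fetch("chr1", 80, 119))
        seq[100 - 80] = "T"
        flank = reference.fetch("chr1", 101, 101)
        seq[101 - 80] = "A" if flank != "A" else "C"
        call = genotype_read(make_read(pos=80, cigar="40M", seq="".join(seq)),
                             SNV, w)
        assert call.status is ReadStatus.MUT
        assert "possible_larger_event" in call.flags

    def test_low_baseq_turns_ambiguous(self, reference):
        w = snv_window(reference)
        r = self._read_with_base(reference, "T")
        import dataclasses
        r = dataclasses.replace(r, baseq=tuple([10] * len(r.seq)))
        call = genotype_read(r, SNV, w, min_baseq=20)
        assert call.status is ReadStatus.AMBIGUOUS and "low_baseq" in call.flags

    def test_homopolymer_truncation_is_ambiguous(self, reference):
        # read ends inside the A-run at chr1 602..605: the truncated
        # haplotypes coincide, so WT and 1bp-del are indistinguishable
        m = normalize(Mutation("chr1", 601, "CA", "C", MutationType.DEL),
                      reference)
        w = build_window(m, reference)
        r = make_read(pos=580, cigar="24M", reference=reference)  # ends at 603
        trunc = 603 - m.pos + 1
        assert w.ref_hap[:trunc] == w.alt_hap[:trunc]  # oracle
        call = genotype_read(r, m, w, reference=reference)
        assert call.status is ReadStatus.AMBIGUOUS
        assert "truncated_window" in call.flags

    def test_cigar_precedence_over_discordant_sequence(self, reference):
        # CIGAR carries the expected deletion but the sequence over the
        # window reads wild-type: status follows the CIGAR, flagged
        m = normalize(Mutation("chr1", 601, "CA", "C", MutationType.DEL),
                      reference)
        w = build_window(m, reference)
        seq = reference.fetch("chr1", 580, 580 + 39)  # wild-type bases
        r = make_read(pos=580, cigar="22M1D18M", seq=seq)
        call = genotype_read(r, m, w, reference=reference)
        assert call.status is ReadStatus.MUT
        assert call.cigar_evidence is CigarEvidence.EXPECTED_INDEL
        assert "cigar_seq_discordant" in call.flags

    def test_deletion_read_full_span_is_mut(self, reference):
        m = normalize(Mutation("chr1", 601, "CA", "C", MutationType.DEL),
                      reference)
        w = build_window(m, reference)
        seq = (reference.fetch("chr1", 580, 601)
               + reference.fetch("chr1", 603, 620))
        r = make_read(pos=580, cigar="22M1D18M", seq=seq)
        call = genotype_read(r, m, w, reference=reference)
        assert call.status is ReadStatus.MUT
        assert "cigar_seq_discordant" not in call.flags


class TestGenotypeFragment:
    CASES = [
        ((ReadStatus.MUT, ReadStatus.MUT), FragmentStatus.MUT, Resolution.CONCORDANT),
        ((ReadStatus.WT, ReadStatus.WT), FragmentStatus.WT, Resolution.CONCORDANT),
        ((ReadStatus.OTH, ReadStatus.OTH), FragmentStatus.OTH, Resolution.CONCORDANT),
        ((ReadStatus.AMBIGUOUS, ReadStatus.WT), FragmentStatus.WT, Resolution.FLAG_RESOLVED),
        ((ReadStatus.MUT, ReadStatus.AMBIGUOUS), FragmentStatus.MUT, Resolution.FLAG_RESOLVED),
        ((ReadStatus.MUT, ReadStatus.WT), FragmentStatus.NI, Resolution.DISCREPANT),
        ((ReadStatus.MUT, ReadStatus.OTH), FragmentStatus.NI, Resolution.DISCREPANT),
        ((ReadStatus.WT, ReadStatus.OTH), FragmentStatus.NI, Resolution.DISCREPANT),
        ((ReadStatus.AMBIGUOUS, ReadStatus.AMBIGUOUS), FragmentStatus.NI, Resolution.AMBIGUOUS),
    ]

    @pytest.mark.parametrize("pair,status,resolution", CASES)
    def test_pair_aggregation(self, pair, status, resolution):
        call = genotype_fragment(ReadCall(pair[0]), ReadCall(pair[1]))
        assert (call.status, call.resolution) == (status, resolution)

    def test_single_read(self):
        call = genotype_fragment(ReadCall(ReadStatus.MUT), None)
        assert (call.status, call.resolution) == \
            (FragmentStatus.MUT, Resolution.SINGLE_READ)
        call = genotype_fragment(ReadCall(ReadStatus.AMBIGUOUS), None)
        assert (call.status, call.resolution) == \
            (FragmentStatus.NI, Resolution.AMBIGUOUS)

    def test_no_coverage_mate_treated_as_absent(self):
        nc = ReadCall(ReadStatus.AMBIGUOUS, {"no_coverage"})
        call = genotype_fragment(ReadCall(ReadStatus.WT), nc)
        assert (call.status, call.resolution) == \
            (FragmentStatus.WT, Resolution.SINGLE_READ)

    def test_ni_iff_discrepant_or_ambiguous(self):
        for pair, status, resolution in self.CASES:
            assert (status is FragmentStatus.NI) == \
                (resolution in (Resolution.DISCREPANT, Resolution.AMBIGUOUS))


class TestLocusVaf:
    def _calls(self, statuses):
        res = {FragmentStatus.NI: Resolution.DISCREPANT}
        return [FragmentCall(s, res.get(s, Resolution.CONCORDANT))
                for s in statuses]

    def test_examples(self):
        v = locus_vaf(self._calls([FragmentStatus.MUT, FragmentStatus.MUT,
                                   FragmentStatus.WT, FragmentStatus.WT,
                                   FragmentStatus.NI]))
        assert (v.vaf, v.n_ni) == (0.5, 1)
        assert locus_vaf(self._calls([FragmentStatus.NI] * 3)).vaf is None
        v = locus_vaf(self._calls([FragmentStatus.MUT, FragmentStatus.WT,
                                   FragmentStatus.WT, FragmentStatus.OTH]))
        assert v.vaf == 0.25  # OTH counts in the denominator

    def test_partition(self):
        statuses = [FragmentStatus.MUT, FragmentStatus.WT, FragmentStatus.OTH,
                    FragmentStatus.NI] * 7
        v = locus_vaf(self._calls(statuses))
        assert v.n_mut + v.n_wt + v.n_oth + v.n_ni == len(statuses)


class TestRepresentationInvariance:
    def test_calls_identical_across_input_representations(self, reference):
        from fragtyper.simdata import enumerate_equivalent_representations
        m = normalize(Mutation("chr1", 601, "CA", "C", MutationType.DEL),
                      reference)
        reads = [
            make_read(pos=580, cigar="22M1D18M",
                      seq=(reference.fetch("chr1", 580, 601)
                           + reference.fetch("chr1", 603, 620))),
            make_read(pos=580, cigar="40M", reference=reference),
            make_read(pos=580, cigar="24M", reference=reference),
        ]
        baseline = None
        for rep in enumerate_equivalent_representations(m, reference):
            mm = normalize(resolve_alleles(rep, reference), reference)
            w = build_window(mm, reference)
            calls = tuple(genotype_read(r, mm, w, reference=reference).status
                          for r in reads)
            if baseline is None:
                baseline = calls
            assert calls == baseline
        assert baseline == (ReadStatus.MUT, ReadStatus.WT, ReadStatus.AMBIGUOUS)
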