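"""Read classification, direct/haploblock/allelic-imbalance constellations."""

import pysam
import pytest
from scipy import stats

from copyphase.model import CnaSegment, Origin, SampleMeta, SmallVariant
from copyphase.phasing import (
    AipDisabledError,
    PairEvidence,
    PhasedSnp,
    ReadObservation,
    _aip_placement,
    _allele_call,
    aip_constellation,
    anchor_constellation,
    collect_pair_evidence,
    direct_constellation,
    haploblock_constellation,
    merge_evidence,
)

from conftest import TOY_REF, sam_to_bam

V1 = SmallVariant(chrom="chrT", pos=10, ref="A", alt="C", origin="somatic",
                  vaf_tumor=0.5, variant_id="v1")
V2 = SmallVariant(chrom="chrT", pos=30, ref="G", alt="T", origin="somatic",
                  vaf_tumor=0.5, variant_id="v2")


class TestCollectPairEvidence:
    def test_manual_pileup_oracle(self, toy_bam):
        """Categories of the handcrafted fragments match a manual pileup:
        the low-quality fragments are dropped and the split mate pair yields
        exactly one ``both`` observation."""
        with pysam.AlignmentFile(str(toy_bam)) as bam:
            ev = collect_pair_evidence(V1, V2, bam)
        by_frag = {o.fragment_id: o.category for o in ev.observations}
        assert by_frag == {
            "r_both": "both",
            "r_mut1": "mut1",
            "r_mut2": "mut2",
            "r_none": "none",
            "p_both": "both",
        }
        assert (ev.n_both, ev.n_mut1, ev.n_mut2, ev.n_none) == (2, 1, 1, 1)

    def test_category_partition(self, toy_bam):
        """Every surviving covering fragment lands in exactly one category."""
        with pysam.AlignmentFile(str(toy_bam)) as bam:
            ev = collect_pair_evidence(V1, V2, bam)
        assert ev.n_both + ev.n_mut1 + ev.n_mut2 + ev.n_none == len(ev.observations)
        assert ev.w_both <= ev.n_both and ev.w_mut1 <= ev.n_mut1

    def test_quality_weights_are_phred_derived(self, toy_bam):
        with pysam.AlignmentFile(str(toy_bam)) as bam:
            ev = collect_pair_evidence(V1, V2, bam)
        o = next(o for o in ev.observations if o.fragment_id == "r_both")
        assert o.p_basecall_m1 == pytest.approx(10 ** (-40 / 10))  # qual 'I'
        assert o.p_mapq_m1 == pytest.approx(10 ** (-60 / 10))

    def test_different_chromosomes_rejected(self, toy_bam):
        other = SmallVariant(chrom="chr9", pos=30, ref="G", alt="T",
                             origin="somatic", vaf_tumor=0.5)
        with pysam.AlignmentFile(str(toy_bam)) as bam:
            with pytest.raises(ValueError, match="one chromosome"):
                collect_pair_evidence(V1, other, bam)

    def test_no_covering_fragments_is_empty_not_an_error(self, toy_bam):
        far_a = SmallVariant(chrom="chrT", pos=48, ref="C", alt="A",
                             origin="somatic", vaf_tumor=0.5)
        far_b = SmallVariant(chrom="chrT", pos=49, ref="A", alt="G",
                             origin="somatic", vaf_tumor=0.5)
        with pysam.AlignmentFile(str(toy_bam)) as bam:
            ev = collect_pair_evidence(far_a, far_b, bam)
        assert ev.observations == []


def _read_from_string(line: str) -> pysam.AlignedSegment:
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chrT", "LN": 100}]}
    )
    return pysam.AlignedSegment.fromstring(line, header)


class TestAlleleCall:
    def test_indel_alleles_via_cigar(self):
        """A deletion in the read supports the deletion allele; a full match
        supports REF; a spliced gap covers neither."""
        ref = TOY_REF
        deletion = SmallVariant(chrom="chrT", pos=10, ref=ref[9:12], alt=ref[9],
                                origin="somatic", vaf_tumor=0.5)
        del_seq = ref[5:10] + ref[12:25]
        del_read = _read_from_string(
            f"rd\t0\tchrT\t6\t60\t5M2D13M\t*\t0\t0\t{del_seq}\t{'I' * len(del_seq)}"
        )
        match_seq = ref[5:25]
        match_read = _read_from_string(
            f"rm\t0\tchrT\t6\t60\t20M\t*\t0\t0\t{match_seq}\t{'I' * 20}"
        )
        assert _allele_call(del_read, deletion, 20)[0] == "alt"
        assert _allele_call(match_read, deletion, 20)[0] == "ref"

        insertion = SmallVariant(chrom="chrT", pos=10, ref=ref[9], alt=ref[9] + "TT",
                                 origin="somatic", vaf_tumor=0.5)
        ins_seq = ref[5:10] + "TT" + ref[10:23]
        ins_read = _read_from_string(
            f"ri\t0\tchrT\t6\t60\t5M2I13M\t*\t0\t0\t{ins_seq}\t{'I' * len(ins_seq)}"
        )
        assert _allele_call(ins_read, insertion, 20)[0] == "alt"
        assert _allele_call(match_read, insertion, 20)[0] == "ref"

    def test_spliced_gap_means_uncovered(self):
        ref = TOY_REF
        snv = SmallVariant(chrom="chrT", pos=10, ref="A", alt="C",
                           origin="somatic", vaf_tumor=0.5)
        seq = ref[5:8] + ref[18:28]
        rna_read = _read_from_string(
            f"rr\t0\tchrT\t6\t60\t3M10N10M\t*\t0\t0\t{seq}\t{'I' * len(seq)}"
        )
        assert _allele_call(rna_read, snv, 20) is None


class TestDirectConstellation:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((3, 0, 0, 0), "same"),
            ((0, 2, 4, 0), "diff"),
            ((2, 1, 0, 0), "undefined"),  # matches neither pattern
            ((0, 0, 0, 5), "undefined"),  # only uninformative reads
            ((0, 0, 0, 0), "undefined"),  # no evidence at all
        ],
    )
    def test_patterns(self, counts, expected):
        ev = PairEvidence(variant_a="a", variant_b="b")
        for cat, n in zip(("both", "mut1", "mut2", "none"), counts):
            ev.observations += [
                ReadObservation(fragment_id=f"{cat}{i}", category=cat,
                                p_basecall_m1=0, p_basecall_m2=0,
                                p_mapq_m1=0, p_mapq_m2=0)
                for i in range(n)
            ]
        call = direct_constellation(ev)
        assert call.relation == expected
        if expected == "undefined":
            assert call.confidence == 0.0
        else:
            assert call.confidence > 0

    def test_symmetric_under_variant_swap(self, toy_bam):
        with pysam.AlignmentFile(str(toy_bam)) as bam:
            ev = collect_pair_evidence(V1, V2, bam)
        a = direct_constellation(ev)
        b = direct_constellation(ev.swapped())
        assert a.relation == b.relation
        assert a.confidence == pytest.approx(b.confidence)

    def test_noise_tolerance_relaxes_the_strict_zeros(self):
        ev = PairEvidence(variant_a="a", variant_b="b")
        ev.observations = [
            ReadObservation(fragment_id=f"b{i}", category="both",
                            p_basecall_m1=0, p_basecall_m2=0, p_mapq_m1=0, p_mapq_m2=0)
            for i in range(10)
        ] + [
            ReadObservation(fragment_id="noise", category="mut1",
                            p_basecall_m1=0.5, p_basecall_m2=0.5,
                            p_mapq_m1=0, p_mapq_m2=0)
        ]
        assert direct_constellation(ev, tau=0.0).relation == "undefined"
        assert direct_constellation(ev, tau=0.5).relation == "same"

    def test_rna_pooling_only_resolves_never_flips(self):
        """Consistent DNA evidence keeps its relation when RNA is pooled;
        RNA can settle a pair that DNA alone left undefined."""
        dna = PairEvidence(variant_a="a", variant_b="b")
        dna.observations = [
            ReadObservation(fragment_id=f"d{i}", category="both", source="dna",
                            p_basecall_m1=0, p_basecall_m2=0, p_mapq_m1=0, p_mapq_m2=0)
            for i in range(3)
        ]
        rna_consistent = PairEvidence(variant_a="a", variant_b="b")
        rna_consistent.observations = [
            ReadObservation(fragment_id="r0", category="both", source="rna",
                            p_basecall_m1=0, p_basecall_m2=0, p_mapq_m1=0, p_mapq_m2=0)
        ]
        assert direct_constellation(merge_evidence(dna, rna_consistent)).relation == "same"

        empty_dna = PairEvidence(variant_a="a", variant_b="b")
        assert direct_constellation(empty_dna).relation == "undefined"
        assert direct_constellation(merge_evidence(empty_dna, rna_consistent)).relation == "same"


class TestHaploblockConstellation:
    def _inputs(self, tmp_path):
        # variant v1 (alt on hap1 side) anchored to s1; v2 anchored to s2 on hap2
        ref = TOY_REF
        s1 = PhasedSnp(chrom="chrT", pos=14, ref=ref[13], alt="A", block_id="7", alt_hap=1)
        s2 = PhasedSnp(chrom="chrT", pos=34, ref=ref[33], alt="C", block_id="7", alt_hap=2)

        def window(start1, end1, subs):
            out = list(ref[start1 - 1 : end1])
            for p, b in subs.items():
                out[p - start1] = b
            return "".join(out)

        lines = ["@HD\tVN:1.6\tSO:unsorted", "@SQ\tSN:chrT\tLN:50"]
        # v1 co-occurs with s1's alt; v2 co-occurs with s2's alt
        for i in range(3):
            lines.append(f"a{i}\t0\tchrT\t5\t60\t20M\t*\t0\t0\t{window(5, 24, {10: 'C', 14: 'A'})}\t{'I'*20}")
            lines.append(f"b{i}\t0\tchrT\t25\t60\t20M\t*\t0\t0\t{window(25, 44, {30: 'T', 34: 'C'})}\t{'I'*20}")
        bam = sam_to_bam("\n".join(lines) + "\n", tmp_path, "hap")
        return s1, s2, bam

    def test_opposite_haplotypes_give_diff(self, tmp_path):
        s1, s2, bam = self._inputs(tmp_path)
        with pysam.AlignmentFile(str(bam)) as fh:
            call = haploblock_constellation(V1, V2, [s1, s2], fh)
        assert call.relation == "diff"
        assert call.method == "haploblock"
        assert 0 < call.confidence <= 1

    def test_same_haplotype_gives_same(self, tmp_path):
        s1, s2, bam = self._inputs(tmp_path)
        s2_flipped = PhasedSnp(chrom=s2.chrom, pos=s2.pos, ref=s2.ref, alt=s2.alt,
                               block_id="7", alt_hap=1)
        with pysam.AlignmentFile(str(bam)) as fh:
            call = haploblock_constellation(V1, V2, [s1, s2_flipped], fh)
        assert call.relation == "same"

    def test_missing_anchor_gives_undefined(self, tmp_path):
        s1, s2, bam = self._inputs(tmp_path)
        with pysam.AlignmentFile(str(bam)) as fh:
            call = haploblock_constellation(V1, V2, [s1], fh)
        assert call.relation == "undefined" and call.confidence == 0.0

    def test_placeholder_scales_the_confidence(self, tmp_path):
        s1, s2, bam = self._inputs(tmp_path)
        with pysam.AlignmentFile(str(bam)) as fh:
            full = haploblock_constellation(V1, V2, [s1, s2], fh, placeholder=1.0)
        with pysam.AlignmentFile(str(bam)) as fh:
            half = haploblock_constellation(V1, V2, [s1, s2], fh, placeholder=0.5)
        assert half.confidence == pytest.approx(full.confidence * 0.5)


class TestAnchorRule:
    def test_snp_only_reads_do_not_break_the_anchor(self):
        """Fragments carrying only the SNP (from normal cells or wild-type
        tumor copies) are expected; only variant-carrying fragments decide."""
        ev = PairEvidence(variant_a="v", variant_b="snp")
        ev.observations = [
            ReadObservation(fragment_id=f"b{i}", category="both",
                            p_basecall_m1=0, p_basecall_m2=0, p_mapq_m1=0, p_mapq_m2=0)
            for i in range(3)
        ] + [
            ReadObservation(fragment_id=f"s{i}", category="mut2",
                            p_basecall_m1=0, p_basecall_m2=0, p_mapq_m1=0, p_mapq_m2=0)
            for i in range(4)
        ]
        assert direct_constellation(ev).relation == "undefined"
        assert anchor_constellation(ev).relation == "same"

    def test_variant_never_with_snp_means_opposite_haplotype(self):
        ev = PairEvidence(variant_a="v", variant_b="snp")
        ev.observations = [
            ReadObservation(fragment_id=f"m{i}", category="mut1",
                            p_basecall_m1=0, p_basecall_m2=0, p_mapq_m1=0, p_mapq_m2=0)
            for i in range(3)
        ]
        assert anchor_constellation(ev).relation == "diff"


class TestAip:
    META = SampleMeta(purity=0.8, sex="female")
    SEG = CnaSegment(chrom="chr1", start=0, end=10_000, tcn=3, cn_major=2, cn_minor=1)

    def _germ(self, vaf, vid):
        return SmallVariant(chrom="chr1", pos=100, ref="A", alt="T", origin="germline",
                            vaf_tumor=vaf, vaf_normal=0.5, variant_id=vid)

    def test_disabled_by_default_with_opt_in_hint(self):
        with pytest.raises(AipDisabledError, match="enable"):
            aip_constellation(self._germ(0.6, "a"), self._germ(0.3, "b"),
                              self.SEG, self.META)

    def test_germline_placements_match_exhaustive_likelihoods(self):
        """Oracle: evaluate the binomial likelihood of both placements by hand
        at purity 0.8 and copy numbers 2+1; the ML allele must match."""
        p, tcn, cnorm = 0.8, 3, 2
        denom = p * tcn + (1 - p) * cnorm
        vaf_major = (p * 2 + (1 - p)) / denom
        vaf_minor = (p * 1 + (1 - p)) / denom
        for vaf, want in ((vaf_major, "major"), (vaf_minor, "minor")):
            k = round(vaf * 100)
            lik = {
                allele: stats.binom.pmf(k, 100, ev)
                for allele, ev in (("major", vaf_major), ("minor", vaf_minor))
            }
            oracle = max(lik, key=lik.get)
            got, conf, _ = _aip_placement(self._germ(vaf, "x"), self.SEG, self.META,
                                          depth=100, lr_threshold=10.0)
            assert got == oracle == want
            assert conf > 0.9

    def test_opposite_alleles_give_diff_same_allele_gives_same(self):
        p, tcn, cnorm = 0.8, 3, 2
        denom = p * tcn + (1 - p) * cnorm
        hi = self._germ((p * 2 + (1 - p)) / denom, "hi")
        lo = self._germ((p * 1 + (1 - p)) / denom, "lo")
        call = aip_constellation(hi, lo, self.SEG, self.META, enabled=True)
        assert call.relation == "diff" and call.method == "aip"
        call2 = aip_constellation(hi, self._germ(hi.vaf_tumor, "hi2"),
                                  self.SEG, self.META, enabled=True)
        assert call2.relation == "same"

    def test_timing_ambiguous_somatic_is_undefined(self):
        """In a 2+1 segment a somatic variant on one copy has the same
        expected VAF whether it pre-dates the gain on the minor allele or
        post-dates it — the likelihood ratio is 1 and no allele is called."""
        p, tcn, cnorm = 0.8, 3, 2
        denom = p * tcn + (1 - p) * cnorm
        som = SmallVariant(chrom="chr1", pos=100, ref="A", alt="T", origin="somatic",
                           vaf_tumor=p * 1 / denom, variant_id="s")
        allele, conf, _ = _aip_placement(som, self.SEG, self.META, 100, 10.0)
        assert allele is None and conf == 0.0
        other = self._germ((p * 2 + (1 - p)) / denom, "g")
        call = aip_constellation(som, other, self.SEG, self.META, enabled=True)
        assert call.relation == "undefined" and call.confidence == 0.0

    def test_balanced_segment_cannot_be_phased(self):
        seg = CnaSegment(chrom="chr1", start=0, end=10_000, tcn=2, cn_major=1, cn_minor=1)
        call = aip_constellation(self._germ(0.6, "a"), self._germ(0.4, "b"),
                                 seg, self.META, enabled=True)
        assert call.relation == "undefined"
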