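"""Gene-status logic: iac arithmetic, LOH rules, pre-check, full verdicts."""

import numpy as np
import pytest

from copyphase.affected import AffectedCopies
from copyphase.graph import infer_matrix
from copyphase.model import CnaSegment, GeneInterval, SampleMeta, SmallVariant
from copyphase.phasing import Constellation
from copyphase.status import (
    compound_precheck,
    gene_verdict,
    integrated_affected_copies,
    single_variant_status,
)

META = SampleMeta(purity=1.0, sex="female")
GENE = GeneInterval(gene_id="G", chrom="chr1", start=0, end=10_000)


def seg(tcn, loh=False, homdel=False):
    return CnaSegment(chrom="chr1", start=0, end=10_000, tcn=tcn, loh=loh,
                      homozygous_deletion=homdel)


def var(vid, pos, origin="somatic", vaf=0.5):
    return SmallVariant(chrom="chr1", pos=pos, ref="A", alt="T", origin=origin,
                        vaf_tumor=vaf, vaf_normal=0.5 if origin == "germline" else None,
                        variant_id=vid)


def ac(vid, value, tcn):
    return AffectedCopies(variant_id=vid, ac=value, wt_copies=tcn - value)


class TestIntegratedAffectedCopies:
    @pytest.mark.parametrize(
        "ac1,ac2,relation,expected",
        [(1.2, 0.9, "same", 1.2), (1.2, 0.9, "diff", 2.1), (0.0, 1.7, "same", 1.7)],
    )
    def test_max_and_sum_rules(self, ac1, ac2, relation, expected):
        assert integrated_affected_copies(ac1, ac2, relation) == pytest.approx(expected)

    def test_undefined_relation_is_a_caller_error(self):
        with pytest.raises(ValueError):
            integrated_affected_copies(1.0, 1.0, "undefined")


class TestSingleVariantStatus:
    def test_no_loh_always_leaves_wt_copies(self):
        v = var("m", 100, vaf=1.0)
        assert single_variant_status(v, ac("m", 2.0, 2), seg(2)) == "wt_copies_left"

    def test_somatic_loh_threshold(self):
        v = var("m", 100)
        assert single_variant_status(v, ac("m", 0.8, 1), seg(1, loh=True)) == "all_copies_affected"
        assert single_variant_status(v, ac("m", 0.4, 1), seg(1, loh=True)) == "wt_copies_left"

    @pytest.mark.parametrize(
        "vaf,expected",
        [(0.9, "all_copies_affected"), (0.1, "wt_copies_left"), (0.5, "undefined")],
    )
    def test_germline_loh_direction_of_allele_loss(self, vaf, expected):
        v = var("g", 100, origin="germline", vaf=vaf)
        assert single_variant_status(v, ac("g", 1.0, 1), seg(1, loh=True)) == expected


class TestCompoundPrecheck:
    def test_flagging_arithmetic(self):
        assert compound_precheck([ac("a", 1.0, 4), ac("b", 1.0, 4)], 4) is True
        assert compound_precheck([ac("a", 1.0, 2), ac("b", 1.0, 2)], 2) is False

    def test_needs_at_least_a_pair(self):
        with pytest.raises(ValueError):
            compound_precheck([ac("a", 1.0, 2)], 2)


def _matrix(*cells):
    variants = sorted({v for c in cells for v in (c.variant_a, c.variant_b)})
    return infer_matrix(cells, variants)


class TestGeneVerdict:
    def test_homdel_decides_even_without_variants(self):
        verdict = gene_verdict(GENE, [], {}, [seg(0.0, homdel=True)], None, META)
        assert verdict.status == "all_copies_affected"
        assert verdict.decisive_evidence == "homdel"
        assert verdict.confidence == 1.0

    def test_no_variants_no_homdel_yields_no_verdict(self):
        assert gene_verdict(GENE, [], {}, [seg(2)], None, META) is None

    def test_phased_diff_pair_exhausts_two_copies(self):
        variants = [var("a", 100), var("b", 200)]
        acs = {"a": ac("a", 1.0, 2), "b": ac("b", 1.0, 2)}
        verdict = gene_verdict(GENE, variants, acs, [seg(2)],
                               _matrix(Constellation("a", "b", "diff", 0.9)), META)
        assert verdict.status == "all_copies_affected"
        assert verdict.iac == pytest.approx(2.0)
        assert verdict.decisive_evidence == "phased_pair"
        assert verdict.confidence == pytest.approx(0.9)

    def test_same_pair_leaves_one_copy(self):
        variants = [var("a", 100), var("b", 200)]
        acs = {"a": ac("a", 1.0, 2), "b": ac("b", 1.0, 2)}
        verdict = gene_verdict(GENE, variants, acs, [seg(2)],
                               _matrix(Constellation("a", "b", "same", 0.9)), META)
        assert verdict.status == "wt_copies_left"
        assert verdict.wt_copies_remaining == pytest.approx(1.0)
        assert verdict.confidence == pytest.approx(0.9)

    def test_unresolved_decisive_pair_is_undefined(self):
        variants = [var("a", 100), var("b", 200)]
        acs = {"a": ac("a", 1.0, 2), "b": ac("b", 1.0, 2)}
        verdict = gene_verdict(GENE, variants, acs, [seg(2)], _matrix(), META)
        assert verdict.status == "undefined"
        assert verdict.confidence == 0.0

    def test_precheck_flag_short_circuits_phasing(self):
        variants = [var("a", 100), var("b", 200)]
        acs = {"a": ac("a", 1.0, 4), "b": ac("b", 1.0, 4)}
        verdict = gene_verdict(GENE, variants, acs, [seg(4)], None, META)
        assert verdict.status == "wt_copies_left"
        assert verdict.flagged is True
        assert verdict.decisive_evidence == "precheck_flag"
        assert verdict.confidence == 1.0

    def test_threshold_is_sharp_at_half_a_copy(self):
        """Sweeping the somatic VAF under LOH, the verdict flips exactly when
        the remaining wild-type copies drop below 0.5; at exactly 0.5 the
        strict reading keeps wild-type copies."""
        tcn = 2.0
        statuses = {}
        for wt in np.arange(0.0, 1.01, 0.05):
            a = tcn - wt
            v = var("m", 100, vaf=a / tcn)
            verdict = gene_verdict(GENE, [v], {"m": ac("m", a, tcn)},
                                   [seg(tcn, loh=True)], None, META)
            statuses[round(wt, 2)] = verdict.status
        for wt, status in statuses.items():
            assert status == ("all_copies_affected" if wt < 0.5 else "wt_copies_left"), wt

    def test_adding_a_variant_never_softens_the_verdict(self):
        """Monotone severity: appending a second variant can escalate
        wt_copies_left to all_copies_affected or undefined, never the reverse."""
        base_vars = [var("a", 100)]
        acs1 = {"a": ac("a", 1.0, 2)}
        first = gene_verdict(GENE, base_vars, acs1, [seg(2)], None, META)
        assert first.status == "wt_copies_left"
        both_vars = [var("a", 100), var("b", 200)]
        acs2 = {"a": ac("a", 1.0, 2), "b": ac("b", 1.0, 2)}
        order = {"wt_copies_left": 0, "undefined": 1, "all_copies_affected": 2}
        for matrix in (_matrix(Constellation("a", "b", "diff", 0.9)),
                       _matrix(Constellation("a", "b", "same", 0.9)),
                       _matrix()):
            second = gene_verdict(GENE, both_vars, acs2, [seg(2)], matrix, META)
            assert order[second.status] >= order[first.status]

    def test_verdict_is_invariant_under_variant_order(self):
        variants = [var("a", 100), var("b", 200), var("c", 300)]
        acs = {k: ac(k, 0.9, 2) for k in "abc"}
        matrix = _matrix(
            Constellation("a", "b", "same", 0.9),
            Constellation("b", "c", "same", 0.8),
            Constellation("a", "c", "same", 0.7),
        )
        fwd = gene_verdict(GENE, variants, acs, [seg(2)], matrix, META)
        rev = gene_verdict(GENE, variants[::-1], acs, [seg(2)], matrix, META)
        assert (fwd.status, fwd.confidence) == (rev.status, rev.confidence)

    @pytest.mark.parametrize("tcn", [1.0, 2.0, 3.0, 4.0])
    def test_ploidy_generality(self, tcn):
        """The same decision logic holds for haploid through tetraploid
        segments: a diff pair exhausting all copies is decisive, one copy
        short is not."""
        variants = [var("a", 100), var("b", 200)]
        half = tcn / 2
        acs_full = {"a": ac("a", half, tcn), "b": ac("b", tcn - half, tcn)}
        matrix = _matrix(Constellation("a", "b", "diff", 1.0))
        full = gene_verdict(GENE, variants, acs_full, [seg(tcn)], matrix, META)
        assert full.status == "all_copies_affected"
        acs_partial = {"a": ac("a", half, tcn), "b": ac("b", max(0.0, tcn - half - 1), tcn)}
        partial = gene_verdict(GENE, variants, acs_partial, [seg(tcn)], matrix, META)
        assert partial.status == "wt_copies_left"

    def test_pair_across_segments_uses_the_minimum_tcn(self, caplog):
        seg_low = CnaSegment(chrom="chr1", start=0, end=150, tcn=2)
        seg_high = CnaSegment(chrom="chr1", start=150, end=10_000, tcn=4)
        variants = [var("a", 100), var("b", 200)]
        acs = {"a": ac("a", 1.0, 2), "b": ac("b", 1.0, 4)}
        with caplog.at_level("WARNING"):
            verdict = gene_verdict(GENE, variants, acs, [seg_low, seg_high],
                                   _matrix(Constellation("a", "b", "diff", 1.0)), META)
        assert "minimum tcn" in caplog.text
        assert verdict.status == "all_copies_affected"  # 2 - (1+1) < 0.5
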