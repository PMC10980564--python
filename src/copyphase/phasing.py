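"""Read-backed phasing of variant pairs.

Every sequencing fragment (a read, or a properly named read pair) that covers
the positions of both variants of a pair is classified into one of four
categories: ``both`` (carries both variant alleles), ``mut1``/``mut2`` (only
one) or ``none``.  The category tallies decide the pair's *constellation*:

    same  — the variants sit on the same copy   (n_both >= 1, n_mut1 = n_mut2 = 0)
    diff  — the variants sit on different copies (n_both = 0, n_mut1 >= 1, n_mut2 >= 1)

Anything else — no covering fragments, or a contradictory mixture — is
``undefined`` and is handed to the indirect machinery (bridging variants,
haploblocks, allelic-imbalance genotyping).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pysam
from scipy import stats

from . import confidence as conf
from .model import CnaSegment, Origin, SampleMeta, SmallVariant, expected_normal_copies, normalize_contig

logger = logging.getLogger(__name__)

DEFAULT_MIN_BASEQ = 20
DEFAULT_MIN_MAPQ = 30
#: likelihood ratio below which an allelic-imbalance placement is ambiguous
DEFAULT_AIP_LR_THRESHOLD = 10.0
#: nominal read depth at which the observed VAF is discretized for the
#: binomial genotype likelihood
DEFAULT_AIP_DEPTH = 100

RELATIONS = ("same", "diff", "undefined")
CATEGORIES = ("both", "mut1", "mut2", "none")


class AipDisabledError(RuntimeError):
    """Raised when allelic-imbalance phasing is invoked without opt-in."""


def phred_to_prob(q: float) -> float:
    """Phred-scaled quality -> error probability, p = 10^(-Q/10)."""
    return 10.0 ** (-q / 10.0)


@dataclass(frozen=True)
class ReadObservation:
    """One fragment's classification at a variant pair, with quality terms."""

    fragment_id: str
    category: str
    p_basecall_m1: float
    p_basecall_m2: float
    p_mapq_m1: float
    p_mapq_m2: float
    source: str = "dna"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown read category {self.category!r}")
        for name in ("p_basecall_m1", "p_basecall_m2", "p_mapq_m1", "p_mapq_m2"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")

    @property
    def weight(self) -> float:
        return conf.read_classification_confidence(self)


@dataclass
class PairEvidence:
    """All fragment observations for one variant pair, with (weighted) tallies."""

    variant_a: str
    variant_b: str
    observations: List[ReadObservation] = field(default_factory=list)

    def _count(self, category: str, weighted: bool) -> float:
        if weighted:
            return sum(o.weight for o in self.observations if o.category == category)
        return sum(1 for o in self.observations if o.category == category)

    @property
    def n_both(self) -> int:
        return int(self._count("both", False))

    @property
    def n_mut1(self) -> int:
        return int(self._count("mut1", False))

    @property
    def n_mut2(self) -> int:
        return int(self._count("mut2", False))

    @property
    def n_none(self) -> int:
        return int(self._count("none", False))

    @property
    def w_both(self) -> float:
        return self._count("both", True)

    @property
    def w_mut1(self) -> float:
        return self._count("mut1", True)

    @property
    def w_mut2(self) -> float:
        return self._count("mut2", True)

    @property
    def w_none(self) -> float:
        return self._count("none", True)

    def swapped(self) -> "PairEvidence":
        """The same evidence with the roles of the two variants exchanged."""
        swap = {"mut1": "mut2", "mut2": "mut1", "both": "both", "none": "none"}
        return PairEvidence(
            variant_a=self.variant_b,
            variant_b=self.variant_a,
            observations=[
                ReadObservation(
                    fragment_id=o.fragment_id,
                    category=swap[o.category],
                    p_basecall_m1=o.p_basecall_m2,
                    p_basecall_m2=o.p_basecall_m1,
                    p_mapq_m1=o.p_mapq_m2,
                    p_mapq_m2=o.p_mapq_m1,
                    source=o.source,
                )
                for o in self.observations
            ],
        )


@dataclass(frozen=True)
class Constellation:
    """Phase relation of a variant pair plus the confidence of the call."""

    variant_a: str
    variant_b: str
    relation: str
    confidence: float
    method: str = "direct"  # direct | indirect | haploblock | aip | imputed

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.relation == "undefined" and self.confidence != 0:
            raise ValueError("undefined constellations carry confidence 0")
        if not 0 <= self.confidence <= 1:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class PhasedSnp:
    """A heterozygous SNP with a phased genotype inside a haploblock.

    ``alt_hap`` names the haplotype (1 or 2) that carries the alternative
    allele, as encoded by a phased VCF genotype (``1|0`` -> 1, ``0|1`` -> 2);
    ``block_id`` is the phase set (PS tag).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    block_id: str
    alt_hap: int

    def __post_init__(self) -> None:
        if self.alt_hap not in (1, 2):
            raise ValueError(f"alt_hap must be 1 or 2, got {self.alt_hap}")

    @property
    def snp_id(self) -> str:
        return f"snp:{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def as_variant(self) -> SmallVariant:
        return SmallVariant(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            origin=Origin.germline,
            vaf_tumor=None,
            vaf_normal=0.5,
            variant_id=self.snp_id,
        )


# ---------------------------------------------------------------------------
# fragment-level allele extraction
# ---------------------------------------------------------------------------

_OP_DEL = 2
_OP_REF_SKIP = 3


def _allele_call(read: pysam.AlignedSegment, variant: SmallVariant, min_baseq: int):
    """Classify one read at one variant: ('alt'|'ref'|'other', p_basecall).

    Returns ``None`` when the read does not informatively cover the variant
    and ``'lowqual'`` when the supporting base is below the quality cutoff.
    CIGAR-aware: deletions and insertions in the read are matched against
    Indel alleles; reference skips (spliced RNA alignments) make the position
    uncovered rather than look like a deletion.
    """
    pos0 = variant.pos0
    ref, alt = variant.ref, variant.alt
    span_end = pos0 + len(ref)  # last ref base consumed by the REF allele
    if read.reference_start > pos0 or read.reference_end is None or read.reference_end < span_end + 1:
        # require the read to reach one base past the ref allele so that a
        # terminal partial deletion cannot masquerade as the full event
        if not (variant.is_snv and read.reference_start <= pos0 < (read.reference_end or 0)):
            return None

    by_ref: Dict[int, Tuple[Optional[int], int]] = {}
    insertions: Dict[int, List[int]] = {}
    last_ref: Optional[int] = None
    for qpos, rpos, op in read.get_aligned_pairs(with_cigar=True):
        op = int(op)
        if rpos is not None:
            by_ref[rpos] = (qpos, op)
            last_ref = rpos
        elif qpos is not None and last_ref is not None:
            insertions.setdefault(last_ref, []).append(qpos)

    seq = read.query_sequence
    quals = read.query_qualities

    def base_at(rpos: int):
        entry = by_ref.get(rpos)
        if entry is None:
            return None
        qpos, op = entry
        if op == _OP_REF_SKIP:
            return None  # spliced out: not covered
        if qpos is None:
            return ("-", None)  # deleted in the read
        return (seq[qpos], quals[qpos] if quals is not None else 30)

    anchor = base_at(pos0)
    if anchor is None:
        return None
    anchor_base, anchor_q = anchor

    if variant.is_snv:
        if anchor_base == "-":
            return ("other", 0.5)
        if anchor_q is not None and anchor_q < min_baseq:
            return "lowqual"
        p_bc = phred_to_prob(anchor_q if anchor_q is not None else 30)
        if anchor_base == alt:
            return ("alt", p_bc)
        if anchor_base == ref:
            return ("ref", p_bc)
        return ("other", p_bc)

    if len(ref) > len(alt):  # deletion; VCF-anchored, alt is the retained prefix
        if anchor_base == "-":
            return ("other", 0.5)
        if anchor_q is not None and anchor_q < min_baseq:
            return "lowqual"
        p_bc = phred_to_prob(anchor_q if anchor_q is not None else 30)
        states = [base_at(r) for r in range(pos0 + 1, span_end)]
        if any(s is None for s in states):
            return None
        if all(s[0] == "-" for s in states) and anchor_base == alt[0]:
            return ("alt", p_bc)
        if anchor_base == ref[0] and all(
            s[0] == ref[i + 1] for i, s in enumerate(states)
        ):
            return ("ref", p_bc)
        return ("other", p_bc)

    # insertion: alt = anchor base + inserted sequence
    if anchor_base == "-":
        return ("other", 0.5)
    if anchor_q is not None and anchor_q < min_baseq:
        return "lowqual"
    p_bc = phred_to_prob(anchor_q if anchor_q is not None else 30)
    inserted = "".join(seq[q] for q in insertions.get(pos0, []))
    if anchor_base == alt[0] and inserted == alt[1:]:
        return ("alt", p_bc)
    if not inserted and anchor_base == ref[0]:
        return ("ref", p_bc)
    return ("other", p_bc)


def _combine_mate_calls(calls: List[Tuple[str, float, float]]):
    """Merge per-read calls of one fragment at one variant.

    ``calls`` holds (allele, p_basecall, p_mapq) from each mate that covers
    the position.  Agreeing mates reinforce each other (minimum error
    probabilities); mates that disagree on alt-presence make the fragment
    uninterpretable at this site.
    """
    if not calls:
        return None
    alt_votes = {c[0] == "alt" for c in calls}
    if len(alt_votes) > 1:
        return ("conflict", max(c[1] for c in calls), max(c[2] for c in calls))
    allele = "alt" if alt_votes == {True} else "ref"
    return (allele, min(c[1] for c in calls), min(c[2] for c in calls))


def collect_pair_evidence(
    variant_a: SmallVariant,
    variant_b: SmallVariant,
    alignments: pysam.AlignmentFile,
    source: str = "dna",
    min_baseq: int = DEFAULT_MIN_BASEQ,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> PairEvidence:
    """Classify every fragment covering both variant positions.

    Fragments covering only one of the positions are ignored.  A read pair
    sharing a query name counts as one fragment and yields exactly one
    observation; mates disagreeing at a position make the fragment ``none``
    (uninterpretable, logged).  Positions supported only by sub-cutoff base
    qualities drop the whole fragment.
    """
    if normalize_contig(variant_a.chrom) != normalize_contig(variant_b.chrom):
        raise ValueError("pair evidence requires both variants on one chromosome")
    evidence = PairEvidence(variant_a=variant_a.variant_id, variant_b=variant_b.variant_id)

    # one fetch over the span of both variants; reads are grouped by name
    contig = variant_a.chrom
    if contig not in alignments.references:
        alt_name = normalize_contig(contig)
        contig = next(
            (r for r in alignments.references if normalize_contig(r) == alt_name),
            contig,
        )
    lo = min(variant_a.pos0, variant_b.pos0)
    hi = max(variant_a.pos0 + len(variant_a.ref), variant_b.pos0 + len(variant_b.ref)) + 1
    fragments: Dict[str, Dict[str, List[Tuple[str, float, float]]]] = {}
    dropped: set = set()
    try:
        reads = alignments.fetch(contig, max(0, lo - 1), hi)
    except ValueError as exc:
        raise ValueError(
            f"alignment source must be indexed for random access: {exc}"
        ) from exc
    for read in reads:
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
        ):
            continue
        if read.mapping_quality < min_mapq:
            continue
        p_mq = phred_to_prob(read.mapping_quality)
        slot = fragments.setdefault(read.query_name, {"a": [], "b": []})
        for key, variant in (("a", variant_a), ("b", variant_b)):
            call = _allele_call(read, variant, min_baseq)
            if call is None:
                continue
            if call == "lowqual":
                dropped.add(read.query_name)
                continue
            allele, p_bc = call
            slot[key].append((allele, p_bc, p_mq))

    for name, slot in sorted(fragments.items()):
        if name in dropped:
            continue
        call_a = _combine_mate_calls(slot["a"])
        call_b = _combine_mate_calls(slot["b"])
        if call_a is None or call_b is None:
            continue  # fragment does not cover both positions
        conflict = call_a[0] == "conflict" or call_b[0] == "conflict"
        if conflict:
            logger.warning(
                "fragment %s: mates disagree at a variant position; classified none",
                name,
            )
        a_alt = call_a[0] == "alt"
        b_alt = call_b[0] == "alt"
        if conflict:
            category = "none"
        elif a_alt and b_alt:
            category = "both"
        elif a_alt:
            category = "mut1"
        elif b_alt:
            category = "mut2"
        else:
            category = "none"
        evidence.observations.append(
            ReadObservation(
                fragment_id=name,
                category=category,
                p_basecall_m1=call_a[1],
                p_basecall_m2=call_b[1],
                p_mapq_m1=call_a[2],
                p_mapq_m2=call_b[2],
                source=source,
            )
        )
    return evidence


def merge_evidence(*parts: PairEvidence) -> PairEvidence:
    """Pool observations from several sources (e.g. DNA + RNA) for one pair."""
    if not parts:
        raise ValueError("nothing to merge")
    head = parts[0]
    merged = PairEvidence(variant_a=head.variant_a, variant_b=head.variant_b)
    for part in parts:
        if (part.variant_a, part.variant_b) != (head.variant_a, head.variant_b):
            raise ValueError("evidence refers to different variant pairs")
        merged.observations.extend(part.observations)
    return merged


# ---------------------------------------------------------------------------
# constellation calls
# ---------------------------------------------------------------------------


def direct_constellation(evidence: PairEvidence, tau: float = 0.0) -> Constellation:
    """Decide same/diff from the category tallies of one pair.

    With the default tolerance tau = 0 the patterns are literal: ``same``
    requires at least one ``both`` fragment and exactly zero ``mut1``/``mut2``
    weight; ``diff`` the inverse.  A positive tau allows that much
    confidence-weighted contradicting weight before a pattern is rejected,
    trading strictness for robustness to sequencing noise.
    """
    relation = "undefined"
    if evidence.n_both >= 1 and evidence.w_mut1 <= tau and evidence.w_mut2 <= tau:
        relation = "same"
    elif evidence.n_mut1 >= 1 and evidence.n_mut2 >= 1 and evidence.w_both <= tau:
        relation = "diff"
    c = (
        conf.constellation_confidence(evidence, relation)
        if relation != "undefined"
        else 0.0
    )
    return Constellation(
        variant_a=evidence.variant_a,
        variant_b=evidence.variant_b,
        relation=relation,
        confidence=c,
        method="direct",
    )


def anchor_constellation(evidence: PairEvidence, tau: float = 0.0) -> Constellation:
    """Phase the first variant of a pair onto the allele of a germline event.

    Used when the second member of the pair is a heterozygous SNP (or any
    germline event): reads carrying only the SNP are expected from admixed
    normal cells and from tumor copies without the first variant, so the
    strict pair patterns cannot apply.  Instead only fragments that carry the
    first variant are informative: if they all also carry the SNP allele the
    variant sits on the SNP's haplotype (``same``); if none do, on the other
    (``diff``).  The confidence statistic is evaluated on that reduced
    fragment set.
    """
    reduced = PairEvidence(
        variant_a=evidence.variant_a,
        variant_b=evidence.variant_b,
        observations=[o for o in evidence.observations if o.category in ("both", "mut1")],
    )
    relation = "undefined"
    if reduced.n_both >= 1 and reduced.w_mut1 <= tau:
        relation = "same"
    elif reduced.n_mut1 >= 1 and reduced.w_both <= tau:
        relation = "diff"
    c = (
        conf.constellation_confidence(reduced, relation)
        if relation != "undefined"
        else 0.0
    )
    return Constellation(
        variant_a=evidence.variant_a,
        variant_b=evidence.variant_b,
        relation=relation,
        confidence=c,
        method="indirect",
    )


def _anchor_to_blocks(
    variant: SmallVariant,
    snps: Sequence[PhasedSnp],
    alignments: pysam.AlignmentFile,
    min_baseq: int,
    min_mapq: int,
    tau: float,
) -> Dict[str, Tuple[int, float]]:
    """Read-level phase a variant onto haploblock haplotypes.

    Returns block_id -> (haplotype carrying the variant, anchor confidence),
    keeping the first successful anchor per block, nearest SNP first.
    """
    anchors: Dict[str, Tuple[int, float]] = {}
    usable = [
        s
        for s in snps
        if normalize_contig(s.chrom) == normalize_contig(variant.chrom)
        and s.pos != variant.pos
    ]
    for snp in sorted(usable, key=lambda s: (abs(s.pos - variant.pos), s.pos)):
        if snp.block_id in anchors:
            continue
        ev = collect_pair_evidence(
            variant, snp.as_variant(), alignments, min_baseq=min_baseq, min_mapq=min_mapq
        )
        call = anchor_constellation(ev, tau=tau)
        if call.relation == "same":
            anchors[snp.block_id] = (snp.alt_hap, call.confidence)
        elif call.relation == "diff":
            anchors[snp.block_id] = (3 - snp.alt_hap, call.confidence)
    return anchors


def haploblock_constellation(
    variant_a: SmallVariant,
    variant_b: SmallVariant,
    snps: Sequence[PhasedSnp],
    alignments: pysam.AlignmentFile,
    placeholder: float = conf.DEFAULT_HAPLOBLOCK_PLACEHOLDER,
    min_baseq: int = DEFAULT_MIN_BASEQ,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    tau: float = 0.0,
) -> Constellation:
    """Phase a distant pair through SNPs of a shared haploblock.

    Each variant is read-level phased to at least one SNP of a block; if both
    variants land on haplotypes of the same block, the pair relation follows
    (same haplotype -> same, opposite -> diff).  The confidence is the product
    of the two anchor confidences and the haploblock placeholder factor.
    """
    anchors_a = _anchor_to_blocks(variant_a, snps, alignments, min_baseq, min_mapq, tau)
    anchors_b = _anchor_to_blocks(variant_b, snps, alignments, min_baseq, min_mapq, tau)
    for block in sorted(set(anchors_a) & set(anchors_b)):
        hap_a, conf_a = anchors_a[block]
        hap_b, conf_b = anchors_b[block]
        relation = "same" if hap_a == hap_b else "diff"
        return Constellation(
            variant_a=variant_a.variant_id,
            variant_b=variant_b.variant_id,
            relation=relation,
            confidence=conf.combine_pair_confidence(
                [conf_a, conf_b], used_haploblock=True, placeholder=placeholder
            ),
            method="haploblock",
        )
    return Constellation(
        variant_a=variant_a.variant_id,
        variant_b=variant_b.variant_id,
        relation="undefined",
        confidence=0.0,
        method="haploblock",
    )


# ---------------------------------------------------------------------------
# allelic-imbalance phasing (AIP) — expert opt-in
# ---------------------------------------------------------------------------


def _aip_placement(
    variant: SmallVariant,
    segment: CnaSegment,
    meta: SampleMeta,
    depth: int,
    lr_threshold: float,
):
    """Maximum-likelihood allele placement of one variant in an imbalanced segment.

    Candidate placements carry k variant copies in the tumor: germline
    variants sit on the major or the minor allele (k = cn_major or cn_minor,
    one normal copy contributing); somatic variants additionally may postdate
    the copy-number event (k = 1 on either allele, no normal contribution).
    The observed VAF, discretized at a nominal depth, is scored with a
    binomial likelihood at each placement's expected VAF.  Placements whose
    best-vs-competitor likelihood ratio falls below the threshold — notably
    the timing-ambiguous somatic case — return no allele.
    """
    p = meta.purity
    cnorm = expected_normal_copies(variant.chrom, meta.sex)
    denom = p * segment.tcn + (1 - p) * cnorm
    if denom <= 0 or variant.vaf_tumor is None:
        return None, 0.0, {}

    placements: Dict[str, Tuple[str, float]] = {}  # name -> (allele, expected VAF)
    if variant.origin is Origin.germline:
        placements["major"] = ("major", (p * segment.cn_major + (1 - p) * 1.0) / denom)
        placements["minor"] = ("minor", (p * segment.cn_minor + (1 - p) * 1.0) / denom)
    else:
        placements["major_pre"] = ("major", p * segment.cn_major / denom)
        placements["minor_pre"] = ("minor", p * segment.cn_minor / denom)
        placements["post"] = (None, p * 1.0 / denom)  # allele unidentifiable

    k_obs = int(round(variant.vaf_tumor * depth))
    liks: Dict[str, float] = {}
    for name, (_, evaf) in placements.items():
        evaf = min(max(evaf, 1e-9), 1 - 1e-9)
        liks[name] = float(stats.binom.pmf(k_obs, depth, evaf))

    best = max(sorted(liks), key=lambda n: liks[n])
    best_allele = placements[best][0]
    if best_allele is None:
        return None, 0.0, liks
    competitors = [
        liks[n] for n in liks if n != best and placements[n][0] != best_allele
    ]
    top_rival = max(competitors) if competitors else 0.0
    if top_rival > 0 and liks[best] / top_rival < lr_threshold:
        return None, 0.0, liks
    if liks[best] == 0:
        return None, 0.0, liks
    posterior = conf.aip_confidence([liks[best]] + competitors)
    return best_allele, posterior, liks


def aip_constellation(
    variant_a: SmallVariant,
    variant_b: SmallVariant,
    segment: CnaSegment,
    meta: SampleMeta,
    enabled: bool = False,
    depth: int = DEFAULT_AIP_DEPTH,
    lr_threshold: float = DEFAULT_AIP_LR_THRESHOLD,
) -> Constellation:
    """Phase two variants of an allelic-imbalance segment by genotype likelihood.

    Disabled by default: allele frequencies of somatic variants depend on the
    unknown order of copy-number and point-mutation events, so this route is
    generally low confidence.  Pass ``enabled=True`` to opt in.
    """
    if not enabled:
        raise AipDisabledError(
            "allelic-imbalance phasing is disabled by default; pass enabled=True "
            "(CLI: --enable-aip) to opt in as an expert user"
        )
    if not segment.allelic_imbalance:
        return Constellation(
            variant_a=variant_a.variant_id,
            variant_b=variant_b.variant_id,
            relation="undefined",
            confidence=0.0,
            method="aip",
        )
    allele_a, conf_a, _ = _aip_placement(variant_a, segment, meta, depth, lr_threshold)
    allele_b, conf_b, _ = _aip_placement(variant_b, segment, meta, depth, lr_threshold)
    if allele_a is None or allele_b is None:
        return Constellation(
            variant_a=variant_a.variant_id,
            variant_b=variant_b.variant_id,
            relation="undefined",
            confidence=0.0,
            method="aip",
        )
    return Constellation(
        variant_a=variant_a.variant_id,
        variant_b=variant_b.variant_id,
        relation="same" if allele_a == allele_b else "diff",
        confidence=conf_a * conf_b,
        method="aip",
    )
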