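"""Per-gene verdicts: do unmutated copies of the gene remain?

The verdict integrates three layers of evidence in a fixed order of priority:

1. a homozygous deletion overlapping the gene — no copies remain at all;
2. single variants: under LOH a lone somatic variant affects all copies when
   it leaves fewer than 0.5 wild-type copies (c_tum - ac < 0.5); a lone
   germline variant does when its tumor allele frequency exceeds 0.5 (the
   other parental allele was the one lost).  Without LOH a single small
   variant can never reach the second allele;
3. pairs of variants (compound events): the pair's phase relation converts
   the two per-variant affected-copy numbers into *integrated affected
   copies* — max(ac1, ac2) when the variants share a copy, ac1 + ac2 when
   they sit on different copies — and fewer than 0.5 remaining wild-type
   copies means all copies are hit.

Before any phasing is attempted, a pre-check asks whether even the maximal
(all-different-copies) assumption could exhaust the gene's copies; if not,
wild-type copies are guaranteed to remain, the gene is flagged, and the
expensive phasing is skipped.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from . import confidence as conf
from .affected import AffectedCopies
from .graph import PhasingMatrix
from .model import (
    CnaSegment,
    GeneInterval,
    Origin,
    SampleMeta,
    SmallVariant,
    normalize_contig,
    segment_at,
)

logger = logging.getLogger(__name__)

#: fewer remaining wild-type copies than this mean none are effectively left
WT_THRESHOLD = 0.5

STATUSES = ("all_copies_affected", "wt_copies_left", "undefined")


@dataclass(frozen=True)
class GeneStatus:
    """Per-gene verdict with its decisive evidence and confidence."""

    gene_id: str
    status: str
    confidence: float
    iac: Optional[float] = None
    wt_copies_remaining: Optional[float] = None
    decisive_evidence: str = "none"
    flagged: bool = False
    n_variants: int = 0
    evidence: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown gene status {self.status!r}")
        if not 0 <= self.confidence <= 1:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


def integrated_affected_copies(ac1: float, ac2: float, relation: str) -> float:
    """iac = max(ac1, ac2) for a same-copy pair, ac1 + ac2 for different copies."""
    if relation == "same":
        return max(ac1, ac2)
    if relation == "diff":
        return ac1 + ac2
    raise ValueError(
        "integrated affected copies is defined only for resolved relations; "
        f"got {relation!r}"
    )


def single_variant_status(
    variant: SmallVariant, ac: AffectedCopies, segment: CnaSegment
) -> str:
    """Verdict contributed by one variant on its own.

    Without LOH: always ``wt_copies_left``.  Under LOH a somatic variant
    affects all copies iff tcn - ac < 0.5; a germline variant iff its tumor
    VAF exceeds 0.5 (below 0.5 the carrying allele was lost).  A germline
    tumor VAF of exactly 0.5 under LOH decides neither direction and is
    ``undefined``.
    """
    if not segment.loh:
        return "wt_copies_left"
    if variant.origin is Origin.somatic:
        if segment.tcn - ac.ac < WT_THRESHOLD:
            return "all_copies_affected"
        return "wt_copies_left"
    vaf = variant.vaf_tumor
    if vaf is None:
        return "undefined"
    if vaf > 0.5:
        return "all_copies_affected"
    if vaf < 0.5:
        return "wt_copies_left"
    return "undefined"


def compound_precheck(acs: Sequence[AffectedCopies], tcn: float) -> bool:
    """True when even all-different-copies pairing cannot exhaust the gene.

    Evaluates iac under the maximal (diff) assumption for every pair; if each
    pair still leaves at least 0.5 wild-type copies, wild-type copies are
    guaranteed, phasing is unnecessary, and the gene is flagged.
    """
    if len(acs) < 2:
        raise ValueError("the compound pre-check needs at least two variants")
    for a, b in itertools.combinations(acs, 2):
        if tcn - integrated_affected_copies(a.ac, b.ac, "diff") < WT_THRESHOLD:
            return False
    return True


def _overlaps(gene: GeneInterval, segment: CnaSegment) -> bool:
    return (
        normalize_contig(gene.chrom) == normalize_contig(segment.chrom)
        and gene.start < segment.end
        and segment.start < gene.end
    )


def gene_verdict(
    gene: GeneInterval,
    variants: Sequence[SmallVariant],
    acs: Mapping[str, AffectedCopies],
    segments: Sequence[CnaSegment],
    matrix: Optional[PhasingMatrix],
    meta: SampleMeta,
) -> Optional[GeneStatus]:
    """Integrate all evidence for one gene into a status.

    Returns ``None`` when there is nothing to decide on (no variants and no
    homozygous deletion).  ``matrix`` supplies pairwise relations for genes
    with several variants; it may be ``None`` when no phasing was run, in
    which case decisive pairs count as unresolved.
    """
    trail: List[str] = []

    homdels = [s for s in segments if s.homozygous_deletion and _overlaps(gene, s)]
    if homdels:
        s = homdels[0]
        full = s.start <= gene.start and gene.end <= s.end
        trail.append(
            f"homozygous deletion {s.chrom}:{s.start}-{s.end} "
            f"({'fully' if full else 'partially'} covering the gene)"
        )
        return GeneStatus(
            gene_id=gene.gene_id,
            status="all_copies_affected",
            confidence=1.0,
            iac=None,
            wt_copies_remaining=0.0,
            decisive_evidence="homdel",
            n_variants=len(variants),
            evidence=tuple(trail),
        )

    usable: List[Tuple[SmallVariant, AffectedCopies, CnaSegment]] = []
    for v in variants:
        seg = segment_at(v, segments)
        ac = acs.get(v.variant_id)
        if seg is None or ac is None:
            trail.append(f"{v.variant_id}: excluded (no covering segment)")
            continue
        usable.append((v, ac, seg))

    if not usable:
        return None

    # (2) single-variant decisions
    single_undefined = False
    wt_candidates: List[float] = []
    for v, ac, seg in usable:
        verdict = single_variant_status(v, ac, seg)
        if verdict == "all_copies_affected":
            decisive = (
                "single_variant_loh" if v.origin is Origin.somatic else "germline_loh"
            )
            trail.append(f"{v.variant_id}: single variant under LOH affects all copies")
            return GeneStatus(
                gene_id=gene.gene_id,
                status="all_copies_affected",
                confidence=1.0,
                iac=ac.ac,
                wt_copies_remaining=max(0.0, seg.tcn - ac.ac),
                decisive_evidence=decisive,
                n_variants=len(usable),
                evidence=tuple(trail),
            )
        if verdict == "undefined":
            single_undefined = True
            trail.append(
                f"{v.variant_id}: germline tumor VAF exactly 0.5 under LOH; "
                "direction of allele loss undecidable"
            )
        else:
            wt_candidates.append(seg.tcn - ac.ac)

    if len(usable) == 1:
        v, ac, seg = usable[0]
        if single_undefined:
            return GeneStatus(
                gene_id=gene.gene_id,
                status="undefined",
                confidence=0.0,
                iac=ac.ac,
                wt_copies_remaining=None,
                decisive_evidence="none",
                n_variants=1,
                evidence=tuple(trail),
            )
        trail.append(f"{v.variant_id}: single variant, logic-decided")
        return GeneStatus(
            gene_id=gene.gene_id,
            status="wt_copies_left",
            confidence=1.0,
            iac=ac.ac,
            wt_copies_remaining=max(0.0, seg.tcn - ac.ac),
            decisive_evidence="none",
            n_variants=1,
            evidence=tuple(trail),
        )

    # (3) compound pre-check under the maximal (diff) assumption
    pairs = list(itertools.combinations(usable, 2))
    pair_tcn = {}
    decisive_pairs = []
    for (va, aca, sa), (vb, acb, sb) in pairs:
        tcn = min(sa.tcn, sb.tcn)
        if sa is not sb and sa.tcn != sb.tcn:
            logger.warning(
                "gene %s: variants %s and %s lie in segments of different copy "
                "number; pair evaluated at the minimum tcn %.3f",
                gene.gene_id, va.variant_id, vb.variant_id, tcn,
            )
        key = (va.variant_id, vb.variant_id)
        pair_tcn[key] = tcn
        if tcn - integrated_affected_copies(aca.ac, acb.ac, "diff") < WT_THRESHOLD:
            decisive_pairs.append(((va, aca), (vb, acb)))
    if not decisive_pairs:
        trail.append(
            "pre-check: no pair can exhaust the gene's copies even if on "
            "different copies; flagged, phasing skipped"
        )
        min_wt = min(
            pair_tcn[(va.variant_id, vb.variant_id)]
            - integrated_affected_copies(aca.ac, acb.ac, "diff")
            for (va, aca, _), (vb, acb, _) in pairs
        )
        return GeneStatus(
            gene_id=gene.gene_id,
            status="wt_copies_left",
            confidence=1.0,
            iac=max(
                integrated_affected_copies(aca.ac, acb.ac, "diff")
                for (va, aca, _), (vb, acb, _) in pairs
            ),
            wt_copies_remaining=max(0.0, min_wt),
            decisive_evidence="precheck_flag",
            flagged=True,
            n_variants=len(usable),
            evidence=tuple(trail),
        )

    # (4)/(5)/(6) phased pairwise evaluation of the decisive pairs
    pair_confidences: Dict[Tuple[str, str], float] = {}
    sufficient: List[Tuple[float, float, float, Tuple[str, str]]] = []
    unresolved: List[Tuple[str, str]] = []
    resolved_wt: List[float] = []
    for (va, aca), (vb, acb) in decisive_pairs:
        key = (va.variant_id, vb.variant_id)
        cell = (
            matrix.get(va.variant_id, vb.variant_id)
            if matrix is not None
            else None
        )
        if cell is None or cell.relation == "undefined":
            unresolved.append(key)
            trail.append(f"pair {key[0]} / {key[1]}: constellation undefined")
            continue
        iac = integrated_affected_copies(aca.ac, acb.ac, cell.relation)
        wt = pair_tcn[key] - iac
        pair_confidences[key] = cell.confidence
        trail.append(
            f"pair {key[0]} / {key[1]}: {cell.relation} ({cell.method}), "
            f"iac={iac:.3f}, wt={wt:.3f}, c_comb={cell.confidence:.4f}"
        )
        if wt < WT_THRESHOLD:
            sufficient.append((cell.confidence, iac, wt, key))
        else:
            resolved_wt.append(wt)

    if sufficient:
        best_conf, iac, wt, key = max(sufficient, key=lambda t: (t[0], t[3]))
        trail.append(f"decisive pair {key[0]} / {key[1]} affects all copies")
        return GeneStatus(
            gene_id=gene.gene_id,
            status="all_copies_affected",
            confidence=conf.gene_confidence(
                "all_copies_affected", {key: best_conf}, "phased_pair"
            ),
            iac=iac,
            wt_copies_remaining=max(0.0, wt),
            decisive_evidence="phased_pair",
            n_variants=len(usable),
            evidence=tuple(trail),
        )

    if unresolved or single_undefined:
        return GeneStatus(
            gene_id=gene.gene_id,
            status="undefined",
            confidence=0.0,
            iac=None,
            wt_copies_remaining=None,
            decisive_evidence="none",
            n_variants=len(usable),
            evidence=tuple(trail),
        )

    min_wt = min(resolved_wt + wt_candidates) if (resolved_wt or wt_candidates) else None
    return GeneStatus(
        gene_id=gene.gene_id,
        status="wt_copies_left",
        confidence=conf.gene_confidence(
            "wt_copies_left", pair_confidences, "phased_pair_set"
        ),
        iac=None,
        wt_copies_remaining=max(0.0, min_wt) if min_wt is not None else None,
        decisive_evidence="phased_pair",
        n_variants=len(usable),
        evidence=tuple(trail),
    )
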