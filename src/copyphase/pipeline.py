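"""End-to-end orchestration: variants + segments + reads -> gene status tables.

Two passes, as the method prescribes: first the per-variant affected copies,
then the per-gene integration (pre-check, phasing of decisive pairs through
reads / bridging SNPs / haploblocks / optional allelic-imbalance genotyping,
verdict and confidence).
"""

from __future__ import annotations

import itertools
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import pysam
from intervaltree import IntervalTree

from . import confidence as conf
from . import io as cpio
from .affected import AffectedCopies, compute_affected_copies, default_normal_vaf
from .graph import DEFAULT_MAX_CHAIN_LENGTH, PhasingMatrix, infer_matrix
from .model import (
    CnaSegment,
    GeneInterval,
    Origin,
    SampleMeta,
    SmallVariant,
    expected_normal_copies,
    normalize_contig,
    segment_at,
)
from .phasing import (
    DEFAULT_AIP_DEPTH,
    DEFAULT_AIP_LR_THRESHOLD,
    DEFAULT_MIN_BASEQ,
    DEFAULT_MIN_MAPQ,
    Constellation,
    PhasedSnp,
    _allele_call,
    aip_constellation,
    anchor_constellation,
    collect_pair_evidence,
    direct_constellation,
    merge_evidence,
)
from .status import GeneStatus, gene_verdict

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_INPUT_ERROR = 2
EXIT_RUNTIME_ERROR = 3


@dataclass
class RunConfig:
    """Everything one run needs; mirrors the CLI flags."""

    somatic_vcf: Optional[os.PathLike | str]
    germline_vcf: Optional[os.PathLike | str]
    segments_tsv: os.PathLike | str
    genes_path: os.PathLike | str
    dna_bam: Optional[os.PathLike | str]
    purity: float
    sex: str
    rna_bam: Optional[os.PathLike | str] = None
    phased_snp_vcf: Optional[os.PathLike | str] = None
    out_dir: Optional[os.PathLike | str] = None
    sample_id: str = "sample"
    tumor_sample: Optional[str] = None
    normal_sample: Optional[str] = None
    enable_aip: bool = False
    haploblock_placeholder: float = conf.DEFAULT_HAPLOBLOCK_PLACEHOLDER
    min_baseq: int = DEFAULT_MIN_BASEQ
    min_mapq: int = DEFAULT_MIN_MAPQ
    noise_tolerance: float = 0.0
    max_chain_length: int = DEFAULT_MAX_CHAIN_LENGTH
    aip_depth: int = DEFAULT_AIP_DEPTH
    aip_lr_threshold: float = DEFAULT_AIP_LR_THRESHOLD
    snp_window: int = 10_000
    par_intervals: Sequence[tuple] = ()
    require_pass: bool = True

    def validate(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        for name in ("somatic_vcf", "germline_vcf", "segments_tsv", "genes_path",
                     "dna_bam", "rna_bam", "phased_snp_vcf"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.somatic_vcf is None and self.germline_vcf is None:
            raise ValueError("at least one of somatic_vcf / germline_vcf is required")


def _pileup_vaf(
    bam: pysam.AlignmentFile, variant: SmallVariant, min_baseq: int, min_mapq: int
) -> Optional[float]:
    """Tumor VAF of a variant recomputed from reads (fallback when the
    germline VCF has no tumor sample)."""
    calls: Dict[str, List[str]] = {}
    contig = variant.chrom
    if contig not in bam.references:
        want = normalize_contig(contig)
        contig = next((r for r in bam.references if normalize_contig(r) == want), contig)
    for read in bam.fetch(contig, max(0, variant.pos0 - 1), variant.pos0 + len(variant.ref) + 1):
        if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
            continue
        if read.mapping_quality < min_mapq:
            continue
        call = _allele_call(read, variant, min_baseq)
        if call is None or call == "lowqual":
            continue
        calls.setdefault(read.query_name, []).append(call[0])
    n_alt = n_total = 0
    for alleles in calls.values():
        votes = set(alleles)
        if "alt" in votes and votes - {"alt"}:
            continue  # discordant mates
        n_total += 1
        if "alt" in votes:
            n_alt += 1
    if n_total == 0:
        return None
    return n_alt / n_total


def _gene_trees(genes: Sequence[GeneInterval]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(normalize_contig(g.chrom), IntervalTree()).addi(
            g.start, g.end, g.gene_id
        )
    return trees


def _pair_edge(
    va: SmallVariant,
    vb: SmallVariant,
    dna: Optional[pysam.AlignmentFile],
    rna: Optional[pysam.AlignmentFile],
    cfg: RunConfig,
    anchor: bool = False,
) -> Constellation:
    """Read-level constellation of two events, DNA and RNA pooled.

    ``anchor=True`` applies the variant-conditioned rule for phasing a
    variant onto a heterozygous germline anchor (SNP).
    """
    parts = []
    if dna is not None:
        parts.append(
            collect_pair_evidence(
                va, vb, dna, source="dna", min_baseq=cfg.min_baseq, min_mapq=cfg.min_mapq
            )
        )
    if rna is not None:
        parts.append(
            collect_pair_evidence(
                va, vb, rna, source="rna", min_baseq=cfg.min_baseq, min_mapq=cfg.min_mapq
            )
        )
    if not parts:
        return Constellation(va.variant_id, vb.variant_id, "undefined", 0.0, "direct")
    merged = merge_evidence(*parts)
    if anchor:
        return anchor_constellation(merged, tau=cfg.noise_tolerance)
    return direct_constellation(merged, tau=cfg.noise_tolerance)


def _phase_gene(
    gene: GeneInterval,
    gene_variants: List[SmallVariant],
    segments_by_vid: Dict[str, CnaSegment],
    snps: List[PhasedSnp],
    dna: Optional[pysam.AlignmentFile],
    rna: Optional[pysam.AlignmentFile],
    meta: SampleMeta,
    cfg: RunConfig,
) -> PhasingMatrix:
    """Build the pairwise phasing matrix for one gene.

    Edges: direct read evidence between the gene's variants, read anchors of
    each variant to phased SNPs near the gene, and haploblock links between
    SNPs of a shared phase set (carrying the user placeholder confidence).
    Unresolved decisive pairs may finally fall back to allelic-imbalance
    genotyping when explicitly enabled.
    """
    targets = [v.variant_id for v in gene_variants]
    near_snps = [
        s
        for s in snps
        if normalize_contig(s.chrom) == normalize_contig(gene.chrom)
        and gene.start - cfg.snp_window <= s.pos - 1 <= gene.end + cfg.snp_window
    ]
    edges: List[Constellation] = []
    for va, vb in itertools.combinations(gene_variants, 2):
        edges.append(_pair_edge(va, vb, dna, rna, cfg))
    for v in gene_variants:
        for s in near_snps:
            edge = _pair_edge(v, s.as_variant(), dna, rna, cfg, anchor=True)
            if edge.relation != "undefined":
                edges.append(edge)
    for sa, sb in itertools.combinations(near_snps, 2):
        if sa.block_id == sb.block_id:
            edges.append(
                Constellation(
                    sa.snp_id,
                    sb.snp_id,
                    "same" if sa.alt_hap == sb.alt_hap else "diff",
                    cfg.haploblock_placeholder,
                    method="haploblock",
                )
            )
    matrix = infer_matrix(edges, targets, max_chain_length=cfg.max_chain_length)

    if cfg.enable_aip:
        for va, vb in itertools.combinations(gene_variants, 2):
            if matrix.get(va.variant_id, vb.variant_id).relation != "undefined":
                continue
            seg_a = segments_by_vid.get(va.variant_id)
            seg_b = segments_by_vid.get(vb.variant_id)
            if seg_a is None or seg_a is not seg_b or not seg_a.allelic_imbalance:
                continue
            cell = aip_constellation(
                va, vb, seg_a, meta,
                enabled=True, depth=cfg.aip_depth, lr_threshold=cfg.aip_lr_threshold,
            )
            if cell.relation != "undefined":
                matrix.set(cell, (va.variant_id, vb.variant_id))
    return matrix


def run_pipeline(cfg: RunConfig) -> Dict[str, pd.DataFrame]:
    """Execute the full method; returns the three result tables.

    ``variants``: per-variant affected copies.  ``pairs``: pairwise phasing
    matrix rows for genes where phasing ran.  ``genes``: the per-gene
    verdicts.  Tables are also written as TSV into ``cfg.out_dir`` when set.
    Deterministic given fixed inputs.
    """
    cfg.validate()
    meta = SampleMeta(purity=cfg.purity, sex=cfg.sex, sample_id=cfg.sample_id)
    if cfg.haploblock_placeholder == conf.DEFAULT_HAPLOBLOCK_PLACEHOLDER:
        logger.info(
            "haploblock confidence placeholder left at its neutral default %.2f; "
            "consider setting it from the confidence of your haploblock caller",
            cfg.haploblock_placeholder,
        )

    segments = cpio.read_segments(cfg.segments_tsv)
    genes = cpio.read_genes(cfg.genes_path)
    variants: List[SmallVariant] = []
    if cfg.somatic_vcf:
        variants += cpio.read_variants(
            cfg.somatic_vcf, Origin.somatic,
            tumor_sample=cfg.tumor_sample, require_pass=cfg.require_pass,
        )
    if cfg.germline_vcf:
        variants += cpio.read_variants(
            cfg.germline_vcf, Origin.germline,
            tumor_sample=cfg.tumor_sample, normal_sample=cfg.normal_sample,
            require_pass=cfg.require_pass,
        )
    snps = cpio.read_phased_snps(cfg.phased_snp_vcf) if cfg.phased_snp_vcf else []

    dna = rna = None
    if cfg.dna_bam:
        dna = pysam.AlignmentFile(str(cpio.prepare_alignments(cfg.dna_bam)))
    if cfg.rna_bam:
        rna = pysam.AlignmentFile(str(cpio.prepare_alignments(cfg.rna_bam)))

    # ---- pass 1: per-variant affected copies -------------------------------
    trees = _gene_trees(genes)
    gene_by_id = {g.gene_id: g for g in genes}
    variant_rows: List[dict] = []
    acs: Dict[str, AffectedCopies] = {}
    segments_by_vid: Dict[str, CnaSegment] = {}
    by_gene: Dict[str, List[SmallVariant]] = {g.gene_id: [] for g in genes}
    n_excluded = n_clamped = 0
    for v in variants:
        gene_hits = sorted(
            iv.data for iv in trees.get(normalize_contig(v.chrom), IntervalTree())[v.pos0]
        )
        seg = segment_at(v, segments)
        row = {
            "variant_id": v.variant_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "origin": v.origin.value,
            "gene_id": ",".join(gene_hits),
            "vaf_tumor": v.vaf_tumor,
            "vaf_normal": v.vaf_normal,
            "tcn": seg.tcn if seg else None,
            "cnorm": None,
            "ac": None,
            "wt_copies": None,
            "clamped": False,
            "excluded_reason": "",
        }
        if seg is None:
            row["excluded_reason"] = "no_covering_segment"
            n_excluded += 1
            variant_rows.append(row)
            continue
        if v.vaf_tumor is None and v.origin is Origin.germline and dna is not None:
            vaf = _pileup_vaf(dna, v, cfg.min_baseq, cfg.min_mapq)
            if vaf is not None:
                v = SmallVariant(
                    chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, origin=v.origin,
                    vaf_tumor=vaf, vaf_normal=v.vaf_normal,
                    variant_id=v.variant_id, zygosity=v.zygosity,
                )
                row["vaf_tumor"] = vaf
        if v.vaf_tumor is None:
            row["excluded_reason"] = "no_tumor_vaf"
            n_excluded += 1
            variant_rows.append(row)
            continue
        cnorm = expected_normal_copies(
            v.chrom, meta.sex, pos=v.pos, par_intervals=cfg.par_intervals
        )
        vv = v
        if v.origin is Origin.germline and v.vaf_normal is None:
            filled = default_normal_vaf(v, meta.sex)
            vv = SmallVariant(
                chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, origin=v.origin,
                vaf_tumor=v.vaf_tumor, vaf_normal=filled,
                variant_id=v.variant_id, zygosity=v.zygosity,
            )
            row["vaf_normal"] = filled
        ac = compute_affected_copies(vv, seg.tcn, cnorm, meta.purity, meta.sex)
        n_clamped += ac.clamped
        acs[v.variant_id] = ac
        segments_by_vid[v.variant_id] = seg
        row.update(cnorm=cnorm, ac=ac.ac, wt_copies=ac.wt_copies, clamped=ac.clamped)
        variant_rows.append(row)
        for gid in gene_hits:
            by_gene[gid].append(vv)

    # ---- pass 2: per-gene integration --------------------------------------
    gene_rows: List[dict] = []
    pair_frames: List[pd.DataFrame] = []
    n_flagged = 0
    for gene in genes:
        gvars = [v for v in by_gene[gene.gene_id] if v.variant_id in acs]
        matrix = None
        from .status import compound_precheck  # local: avoid top-level cycle noise

        needs_phasing = False
        if len(gvars) >= 2:
            gene_acs = [acs[v.variant_id] for v in gvars]
            min_tcn = min(segments_by_vid[v.variant_id].tcn for v in gvars)
            needs_phasing = not compound_precheck(gene_acs, min_tcn)
        if needs_phasing:
            matrix = _phase_gene(
                gene, gvars, segments_by_vid, snps, dna, rna, meta, cfg
            )
            df = matrix.to_dataframe()
            df.insert(0, "gene_id", gene.gene_id)
            pair_frames.append(df)
        verdict = gene_verdict(gene, gvars, acs, segments, matrix, meta)
        if verdict is None:
            continue
        n_flagged += verdict.flagged
        logger.info(
            "gene %s: %s (confidence %.4f, evidence: %s)",
            gene.gene_id, verdict.status, verdict.confidence,
            verdict.decisive_evidence,
        )
        gene_rows.append(
            {
                "gene_id": verdict.gene_id,
                "status": verdict.status,
                "confidence": verdict.confidence,
                "iac": verdict.iac,
                "wt_copies_remaining": verdict.wt_copies_remaining,
                "decisive_evidence": verdict.decisive_evidence,
                "n_variants": verdict.n_variants,
                "flagged": verdict.flagged,
            }
        )

    logger.info(
        "run summary: %d variants (%d excluded, %d clamped), %d genes scored, "
        "%d flagged by the pre-check",
        len(variants), n_excluded, n_clamped, len(gene_rows), n_flagged,
    )

    results = {
        "variants": pd.DataFrame(
            variant_rows,
            columns=["variant_id", "chrom", "pos", "ref", "alt", "origin", "gene_id",
                     "vaf_tumor", "vaf_normal", "tcn", "cnorm", "ac", "wt_copies",
                     "clamped", "excluded_reason"],
        ),
        "pairs": (
            pd.concat(pair_frames, ignore_index=True)
            if pair_frames
            else pd.DataFrame(
                columns=["gene_id", "variant_a", "variant_b", "relation",
                         "confidence", "method", "chain"]
            )
        ),
        "genes": pd.DataFrame(
            gene_rows,
            columns=["gene_id", "status", "confidence", "iac", "wt_copies_remaining",
                     "decisive_evidence", "n_variants", "flagged"],
        ),
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cpio.write_table(results["variants"], out / "variants.tsv")
        cpio.write_table(results["pairs"], out / "pairs.tsv")
        cpio.write_table(results["genes"], out / "genes.tsv")
    if dna is not None:
        dna.close()
    if rna is not None:
        rna.close()
    return results
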