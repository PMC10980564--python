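"""Readers and writers for the standard input/output formats.

Variants come from VCF 4.x (via cyvcf2), copy-number segments from a
tab-separated table, gene intervals from BED4 or GTF, alignments from
coordinate-sorted indexed SAM/BAM (via pysam/samtools).  All output tables
are plain TSV.
"""

from __future__ import annotations

import logging
import os
import tempfile
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

from .model import CnaSegment, GeneInterval, Origin, SmallVariant
from .phasing import PhasedSnp

logger = logging.getLogger(__name__)

_INT32_SENTINEL = -2147483648  # cyvcf2 missing-integer marker


def _fmt_value(arr, sample_idx: int, alt_idx: int):
    if arr is None:
        return None
    row = arr[sample_idx]
    value = row[alt_idx] if np.ndim(row) else row
    if value is None:
        return None
    value = float(value)
    if not np.isfinite(value) or value == _INT32_SENTINEL:
        return None
    return value


def _sample_vaf(rec, sample_idx: int, alt_idx: int) -> Optional[float]:
    """VAF of one alt allele in one sample: FORMAT/AF, then AD/DP, then INFO/AF."""
    af = _fmt_value(rec.format("AF"), sample_idx, alt_idx)
    if af is not None:
        return min(max(af, 0.0), 1.0)
    ad = rec.format("AD")
    if ad is not None:
        alt_depth = _fmt_value(ad, sample_idx, alt_idx + 1)
        dp = _fmt_value(rec.format("DP"), sample_idx, 0)
        if dp is None and ad is not None:
            row = [v for v in np.atleast_1d(ad[sample_idx]) if v >= 0]
            dp = float(sum(row)) if row else None
        if alt_depth is not None and dp:
            return min(max(alt_depth / dp, 0.0), 1.0)
    info_af = rec.INFO.get("AF")
    if info_af is not None:
        if isinstance(info_af, tuple):
            info_af = info_af[alt_idx]
        return min(max(float(info_af), 0.0), 1.0)
    return None


def _pick_samples(
    samples: Sequence[str],
    tumor_sample: Optional[str],
    normal_sample: Optional[str],
) -> Tuple[Optional[int], Optional[int]]:
    """Indices of (tumor, normal) samples; heuristic on names when not given."""

    def find(requested: Optional[str], keyword: str) -> Optional[int]:
        if requested is not None:
            if requested not in samples:
                raise ValueError(f"sample {requested!r} not in VCF samples {list(samples)}")
            return samples.index(requested)
        hits = [i for i, s in enumerate(samples) if keyword in s.lower()]
        return hits[0] if len(hits) == 1 else None

    return find(tumor_sample, "tumor"), find(normal_sample, "normal")


def read_variants(
    path: os.PathLike | str,
    origin: Origin | str,
    *,
    tumor_sample: Optional[str] = None,
    normal_sample: Optional[str] = None,
    require_pass: bool = True,
) -> List[SmallVariant]:
    """Parse small variants from a VCF.

    Multi-allelic records are split into one variant per alt allele.
    Records failing FILTER are excluded (counted in the log) unless
    ``require_pass`` is off.  For somatic calls the tumor VAF is read from
    the tumor sample (the only sample in a single-sample VCF); for germline
    calls the normal sample supplies the control VAF and, if a tumor sample
    is present, its VAF is read as well — otherwise the pipeline later fills
    it from a tumor pileup.
    """
    origin = Origin(origin)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    tumor_idx, normal_idx = _pick_samples(samples, tumor_sample, normal_sample)
    if len(samples) == 1:
        if origin is Origin.somatic:
            tumor_idx = 0
        else:
            normal_idx = 0 if normal_idx is None else normal_idx
    if origin is Origin.somatic and tumor_idx is None and samples:
        raise ValueError(
            f"cannot identify the tumor sample among {samples}; pass tumor_sample="
        )
    if origin is Origin.germline and normal_idx is None and samples:
        raise ValueError(
            f"cannot identify the normal sample among {samples}; pass normal_sample="
        )

    variants: List[SmallVariant] = []
    n_filtered = 0
    for rec in vcf:
        if require_pass and rec.FILTER is not None:  # None == PASS in cyvcf2
            n_filtered += 1
            continue
        gts = rec.genotypes if samples else None
        for alt_idx, alt in enumerate(rec.ALT):
            if not alt or alt == "*":
                continue
            zygosity = None
            if origin is Origin.germline and gts is not None and normal_idx is not None:
                alleles = [a for a in gts[normal_idx][:-1] if a >= 0]
                called = [a == alt_idx + 1 for a in alleles]
                if called and all(called):
                    zygosity = "homozygous"
                elif any(called):
                    zygosity = "heterozygous"
            if origin is Origin.somatic:
                vaf_tumor = _sample_vaf(rec, tumor_idx, alt_idx) if tumor_idx is not None else None
                vaf_normal = None
            else:
                vaf_normal = _sample_vaf(rec, normal_idx, alt_idx) if normal_idx is not None else None
                vaf_tumor = _sample_vaf(rec, tumor_idx, alt_idx) if tumor_idx is not None else None
            vid = rec.ID or ""
            if vid and len(rec.ALT) > 1:
                vid = f"{vid}_{alt}"
            variants.append(
                SmallVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    origin=origin,
                    vaf_tumor=vaf_tumor,
                    vaf_normal=vaf_normal,
                    variant_id=vid,
                    zygosity=zygosity,
                )
            )
    if n_filtered:
        logger.info("%s: excluded %d non-PASS records", path, n_filtered)
    return variants


def read_phased_snps(path: os.PathLike | str) -> List[PhasedSnp]:
    """Heterozygous SNPs with phased genotypes (``|``) and a PS phase-set tag."""
    vcf = VCF(str(path))
    snps: List[PhasedSnp] = []
    for rec in vcf:
        if rec.FILTER is not None or len(rec.ALT) != 1:
            continue
        gt = rec.genotypes[0]
        alleles, phased = gt[:-1], gt[-1]
        if not phased or sorted(alleles) != [0, 1]:
            continue
        ps = rec.format("PS")
        if ps is None or int(ps[0][0]) == _INT32_SENTINEL:
            continue
        snps.append(
            PhasedSnp(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                block_id=str(int(ps[0][0])),
                alt_hap=1 if alleles[0] == 1 else 2,
            )
        )
    return snps


_SEG_BOOL = {"true": True, "false": False, "1": True, "0": False}


def read_segments(path: os.PathLike | str) -> List[CnaSegment]:
    """Copy-number segment table.

    TSV with header ``chrom,start,end,tcn,loh,homdel[,cn_major,cn_minor,
    haploblock_id]``; intervals 0-based half-open, booleans ``true``/``false``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "haploblock_id": str})
    required = {"chrom", "start", "end", "tcn", "loh", "homdel"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"segment table {path} lacks columns: {sorted(missing)}")
    segments = []
    for row in df.itertuples(index=False):
        def as_bool(v) -> bool:
            if isinstance(v, (bool, np.bool_)):
                return bool(v)
            return _SEG_BOOL[str(v).strip().lower()]

        cn_major = getattr(row, "cn_major", None)
        cn_minor = getattr(row, "cn_minor", None)
        if cn_major is not None and (pd.isna(cn_major) or pd.isna(cn_minor)):
            cn_major = cn_minor = None
        block = getattr(row, "haploblock_id", None)
        if block is not None and pd.isna(block):
            block = None
        segments.append(
            CnaSegment(
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                tcn=float(row.tcn),
                loh=as_bool(row.loh),
                homozygous_deletion=as_bool(row.homdel),
                cn_major=None if cn_major is None else float(cn_major),
                cn_minor=None if cn_minor is None else float(cn_minor),
                haploblock_id=block,
            )
        )
    return segments


def read_genes(path: os.PathLike | str) -> List[GeneInterval]:
    """Gene intervals from BED4 (chrom, start, end, gene_id) or GTF."""
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        genes = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9 or fields[2] != "gene":
                    continue
                attrs = fields[8]
                gene_id = None
                for chunk in attrs.split(";"):
                    chunk = chunk.strip()
                    if chunk.startswith("gene_id"):
                        gene_id = chunk.split(None, 1)[1].strip().strip('"')
                        break
                if gene_id is None:
                    raise ValueError(f"GTF gene line without gene_id attribute: {line!r}")
                genes.append(
                    GeneInterval(
                        gene_id=gene_id,
                        chrom=fields[0],
                        start=int(fields[3]) - 1,  # GTF is 1-based inclusive
                        end=int(fields[4]),
                    )
                )
        return genes
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene_id"], usecols=range(4),
        dtype={"chrom": str, "gene_id": str},
    )
    return [
        GeneInterval(gene_id=r.gene_id, chrom=r.chrom, start=int(r.start), end=int(r.end))
        for r in df.itertuples(index=False)
    ]


def prepare_alignments(path: os.PathLike | str, workdir: Optional[os.PathLike] = None) -> Path:
    """Return an indexed, coordinate-sorted BAM for ``path``.

    A plain SAM (or an unindexed BAM) is sorted and indexed into ``workdir``
    (a temporary directory by default); an already-indexed BAM is returned
    as-is.
    """
    path = Path(path)
    if path.suffix == ".bam":
        for idx in (path.with_suffix(".bam.bai"), path.with_suffix(".bai")):
            if idx.exists():
                return path
        if Path(str(path) + ".bai").exists():
            return path
    workdir = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="copyphase_aln_"))
    workdir.mkdir(parents=True, exist_ok=True)
    out = workdir / (path.stem + ".sorted.bam")
    pysam.sort("-o", str(out), str(path))
    pysam.index(str(out))
    return out


def write_table(df: pd.DataFrame, path: os.PathLike | str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
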