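"""Core genomic domain types and the expected-normal-copy-number model.

The whole analysis reasons about copies of a genomic segment in a mixture of
tumor and admixed normal cells.  The types here carry exactly the quantities
that the downstream arithmetic needs: per-variant allele frequencies, per
segment the tumor copy number and its LOH / homozygous-deletion state, and the
sample-level purity and sex.  Coordinates follow the usual split: variant
positions are 1-based (as printed in VCFs), all intervals are 0-based
half-open (as in BED).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

_AUTOSOMES = frozenset(str(i) for i in range(1, 23))


class Sex(str, Enum):
    female = "female"
    male = "male"


class Origin(str, Enum):
    somatic = "somatic"
    germline = "germline"


def normalize_contig(chrom: str) -> str:
    """Canonical contig name: strips a ``chr`` prefix, upper-cases X/Y.

    ``"chr1"`` and ``"1"``, ``"chrX"`` and ``"X"`` refer to the same contig;
    inputs from different tools (VCF, BAM, segment tables) routinely disagree
    on the prefix.
    """
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.upper() in ("X", "Y"):
        return name.upper()
    return name


@dataclass(frozen=True)
class SampleMeta:
    """Sample-level parameters: tumor purity and sex."""

    purity: float
    sex: Sex
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        object.__setattr__(self, "sex", Sex(self.sex))


@dataclass(frozen=True)
class SmallVariant:
    """One SNV or small Indel with its tumor (and, for germline, normal) VAF.

    ``vaf_tumor`` may be ``None`` at construction time for germline variants
    read from a single-sample (normal-only) VCF; the pipeline fills it from a
    tumor-read pileup before any arithmetic runs.  ``zygosity`` is the normal
    genotype hint (``"heterozygous"``/``"homozygous"``) used when the normal
    VAF has to be substituted by its expected value.
    """

    chrom: str
    pos: int  # 1-based, as printed in a VCF
    ref: str
    alt: str
    origin: Origin
    vaf_tumor: Optional[float] = None
    vaf_normal: Optional[float] = None
    gene_id: str = ""
    variant_id: str = ""
    zygosity: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", Origin(self.origin))
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError(
                f"ref/alt must be non-empty and distinct, got {self.ref!r}>{self.alt!r}"
            )
        if self.origin is Origin.somatic and self.vaf_normal is not None:
            raise ValueError("somatic variants carry no normal VAF")
        for name in ("vaf_tumor", "vaf_normal"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.variant_id:
            object.__setattr__(
                self,
                "variant_id",
                f"{self.origin.value[0]}:{self.chrom}:{self.pos}:{self.ref}>{self.alt}",
            )

    @property
    def pos0(self) -> int:
        """0-based position of the first reference base of the variant."""
        return self.pos - 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class CnaSegment:
    """An allele-specific somatic copy-number segment (an input, never called here)."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    tcn: float
    loh: bool = False
    homozygous_deletion: bool = False
    cn_major: Optional[float] = None
    cn_minor: Optional[float] = None
    haploblock_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"segment start must precede end: {self.start}..{self.end}")
        if self.tcn < 0:
            raise ValueError(f"total copy number must be >= 0, got {self.tcn}")
        if (self.cn_major is None) != (self.cn_minor is None):
            raise ValueError("cn_major and cn_minor must be given together")
        if self.cn_major is not None:
            if abs(self.cn_major + self.cn_minor - self.tcn) > 1e-6:
                raise ValueError("allele-specific copy numbers must sum to tcn")
            if not self.cn_major >= self.cn_minor >= 0:
                raise ValueError("require cn_major >= cn_minor >= 0")
        if self.homozygous_deletion and self.tcn >= 0.5:
            raise ValueError("homozygous deletion implies tcn < 0.5")

    def contains(self, chrom: str, pos0: int) -> bool:
        return (
            normalize_contig(chrom) == normalize_contig(self.chrom)
            and self.start <= pos0 < self.end
        )

    @property
    def allelic_imbalance(self) -> bool:
        return (
            self.cn_major is not None
            and self.cn_minor is not None
            and self.cn_major != self.cn_minor
        )


@dataclass(frozen=True)
class GeneInterval:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene start must precede end: {self.start}..{self.end}")


# PAR interval: (chrom, start, end), 0-based half-open, on X or Y.
ParIntervals = Sequence[tuple]


def expected_normal_copies(
    chrom: str,
    sex: Sex | str,
    *,
    pos: Optional[int] = None,
    par_intervals: Optional[ParIntervals] = None,
) -> int:
    """Expected copy number of a locus in normal tissue (c_norm).

    2 for autosomes and for the X chromosome in female samples; 1 for X and Y
    in male samples.  Y is treated as haploid irrespective of stated sex: a Y
    contig, whenever it is present at all, exists in one copy.  If the caller
    supplies pseudoautosomal intervals and a (1-based) position that falls in
    one, male X/Y loci are restored to 2 copies.

    Raises ``ValueError`` for contigs outside autosomes/X/Y (e.g. MT), naming
    the offending contig.
    """
    sex = Sex(sex)
    name = normalize_contig(chrom)
    if name in _AUTOSOMES:
        return 2
    if name not in ("X", "Y"):
        raise ValueError(f"unrecognized contig for ploidy model: {chrom!r}")
    if name == "X" and sex is Sex.female:
        return 2
    if par_intervals and pos is not None:
        pos0 = pos - 1
        for c, s, e in par_intervals:
            if normalize_contig(str(c)) == name and s <= pos0 < e:
                return 2
    return 1


def segment_at(
    variant: SmallVariant, segments: Iterable[CnaSegment]
) -> Optional[CnaSegment]:
    """The copy-number segment a variant falls in, or ``None`` with a warning.

    Segments are expected to be non-overlapping per chromosome; the result is
    independent of their input order.  Variants in uncovered regions are not
    an error — they are excluded from the analysis by the caller.
    """
    hits = sorted(
        (s for s in segments if s.contains(variant.chrom, variant.pos0)),
        key=lambda s: (s.start, s.end),
    )
    if not hits:
        logger.warning(
            "variant %s at %s:%d not covered by any copy-number segment; excluded",
            variant.variant_id,
            variant.chrom,
            variant.pos,
        )
        return None
    if len(hits) > 1:
        logger.warning(
            "variant %s covered by %d overlapping segments; using the first by position",
            variant.variant_id,
            len(hits),
        )
    return hits[0]
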