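"""Per-variant affected copies in a tumor/normal mixture.

A variant's allele frequency in a bulk tumor sample is diluted by reads from
admixed normal cells.  With purity ``p``, segment tumor copy number ``c_tum``
and expected normal copy number ``c_norm``, the number of tumor copies that
carry the variant is

    somatic:   ac = VAF_tum * (c_tum + c_norm * (1/p - 1))
    germline:  ac = VAF_tum * c_tum + (VAF_tum - VAF_norm) * c_norm * (1/p - 1)

Somatic variants contribute no variant reads from normal cells; germline
variants do, which the normal-VAF term subtracts out.  Both formulas assume a
clonal tumor (cancer cell fraction 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .model import Origin, Sex, SmallVariant

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AffectedCopies:
    """Number of tumor copies carrying a variant, and the wild-type remainder.

    ``clamped`` flags results that fell outside the physical range [0, tcn]
    before clamping — a sign of noise or of a violated clonality assumption.
    """

    variant_id: str
    ac: float
    wt_copies: float
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.ac < 0:
            raise ValueError(f"affected copies must be >= 0, got {self.ac}")


def _finalize(variant_id: str, raw_ac: float, tcn: float) -> AffectedCopies:
    ac, clamped = raw_ac, False
    if raw_ac > tcn:
        ac, clamped = tcn, True
        logger.warning(
            "variant %s: affected copies %.3f exceeds segment copy number %.3f; "
            "clamped (clonality assumption likely violated)",
            variant_id, raw_ac, tcn,
        )
    elif raw_ac < 0:
        ac, clamped = 0.0, True
        logger.warning(
            "variant %s: affected copies %.3f below zero; clamped to 0 "
            "(allele likely lost in the tumor)",
            variant_id, raw_ac,
        )
    return AffectedCopies(variant_id=variant_id, ac=ac, wt_copies=tcn - ac, clamped=clamped)


def somatic_affected_copies(
    vaf_tumor: float,
    tcn: float,
    cnorm: float,
    purity: float,
    variant_id: str = "",
) -> AffectedCopies:
    """ac = VAF_tum * (c_tum + c_norm * (1/p - 1)), clamped into [0, tcn]."""
    if purity <= 0:
        raise ValueError("purity must be > 0; a purity-0 sample carries no tumor signal")
    if not 0 <= vaf_tumor <= 1:
        raise ValueError(f"vaf_tumor must be in [0, 1], got {vaf_tumor}")
    if tcn < 0:
        raise ValueError(f"tcn must be >= 0, got {tcn}")
    raw = vaf_tumor * (tcn + cnorm * (1.0 / purity - 1.0))
    return _finalize(variant_id, raw, tcn)


def germline_affected_copies(
    vaf_tumor: float,
    vaf_normal: float,
    tcn: float,
    cnorm: float,
    purity: float,
    variant_id: str = "",
) -> AffectedCopies:
    """ac = VAF_tum * c_tum + (VAF_tum - VAF_norm) * c_norm * (1/p - 1).

    The correction term vanishes when tumor and normal VAF agree; a tumor VAF
    below the normal one signals loss of the carrying allele and drives the
    raw value towards (or below) zero.
    """
    if purity <= 0:
        raise ValueError("purity must be > 0; a purity-0 sample carries no tumor signal")
    for name, v in (("vaf_tumor", vaf_tumor), ("vaf_normal", vaf_normal)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if tcn < 0:
        raise ValueError(f"tcn must be >= 0, got {tcn}")
    raw = vaf_tumor * tcn + (vaf_tumor - vaf_normal) * cnorm * (1.0 / purity - 1.0)
    return _finalize(variant_id, raw, tcn)


def default_normal_vaf(
    variant: SmallVariant,
    sex: Sex | str,
    zygosity_hint: str = "heterozygous",
) -> float:
    """Expected normal VAF when the control VAF is unobserved.

    0.5 for heterozygous variants on autosomes or on female X; 1 for
    homozygous variants and for anything on male X or on Y (hemizygous loci
    have no second allele to dilute the variant).
    """
    sex = Sex(sex)
    hint = variant.zygosity or zygosity_hint
    if hint not in ("heterozygous", "homozygous"):
        raise ValueError(f"unknown zygosity hint {hint!r}")
    from .model import expected_normal_copies

    if expected_normal_copies(variant.chrom, sex) == 1:
        return 1.0
    return 1.0 if hint == "homozygous" else 0.5


def compute_affected_copies(
    variant: SmallVariant,
    tcn: float,
    cnorm: float,
    purity: float,
    sex: Sex | str = Sex.female,
) -> AffectedCopies:
    """Dispatch on variant origin; substitutes the default normal VAF if missing."""
    if variant.vaf_tumor is None:
        raise ValueError(f"variant {variant.variant_id} has no tumor VAF")
    if variant.origin is Origin.somatic:
        return somatic_affected_copies(
            variant.vaf_tumor, tcn, cnorm, purity, variant.variant_id
        )
    vaf_normal = variant.vaf_normal
    if vaf_normal is None:
        vaf_normal = default_normal_vaf(variant, sex)
    return germline_affected_copies(
        variant.vaf_tumor, vaf_normal, tcn, cnorm, purity, variant.variant_id
    )
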