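"""Confidence scores for read classifications, constellations and gene verdicts.

All scores live in [0, 1] with 1 the maximum confidence.  Genes decided by
logic alone (an LOH call, a homozygous deletion, or the compound pre-check)
get confidence 1; genes decided via phasing inherit the product of the
confidences of every phasing step that was needed.

The per-pair constellation score is an empirical measure inspired by the
chi-square goodness-of-fit statistic, not a calibrated test: the
crc-weighted observed category counts are compared against the counts
expected under the *opposite* constellation, so evidence that clearly
contradicts the alternative yields a score near 1.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

from scipy import stats

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, types only
    from .phasing import PairEvidence, ReadObservation

#: pseudocount added to every expected cell of the chi-square-style statistic
DEFAULT_EPSILON = 0.5

#: stand-in confidence factor for haploblock-derived phase links; the
#: upstream haploblock caller's own confidence may be substituted by the user
DEFAULT_HAPLOBLOCK_PLACEHOLDER = 1.0

_LOGIC_EVIDENCE = frozenset(
    {"homdel", "single_variant_loh", "germline_loh", "precheck_flag"}
)


def read_classification_confidence(obs: "ReadObservation") -> float:
    """c_rc = (1-p_bc,m1)(1-p_mq,m1)(1-p_bc,m2)(1-p_mq,m2).

    The product of the per-site basecall and mapping success probabilities of
    the fragment at both variant positions.
    """
    return (
        (1.0 - obs.p_basecall_m1)
        * (1.0 - obs.p_mapq_m1)
        * (1.0 - obs.p_basecall_m2)
        * (1.0 - obs.p_mapq_m2)
    )


def constellation_confidence(
    evidence: "PairEvidence",
    relation: str,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Confidence that the observed read categories support ``relation``.

    Each read is weighted by its classification confidence c_rc, so low
    quality reads contribute less.  The weighted counts over the informative
    categories {both, mut1, mut2} are compared against the counts expected
    under the ALTERNATIVE constellation (same <-> diff) with a
    chi-square-style statistic

        X2 = sum (obs_w - exp_w)^2 / (exp_w + epsilon),

    and the score is 1 - P(Chi2_2 > X2): evidence far from the alternative
    scores near 1.  ``none`` reads are consistent with either constellation
    whenever a wild-type copy exists and are excluded.  Zero informative
    weight yields 0.
    """
    if relation not in ("same", "diff"):
        raise ValueError(f"relation must be 'same' or 'diff', got {relation!r}")
    w_both, w_mut1, w_mut2 = evidence.w_both, evidence.w_mut1, evidence.w_mut2
    total = w_both + w_mut1 + w_mut2
    if total <= 0:
        return 0.0
    if relation == "same":
        expected = (0.0, total / 2.0, total / 2.0)  # the 'diff' pattern
    else:
        expected = (total, 0.0, 0.0)  # the 'same' pattern
    x2 = sum(
        (o - e) ** 2 / (e + epsilon)
        for o, e in zip((w_both, w_mut1, w_mut2), expected)
    )
    return float(min(1.0, max(0.0, 1.0 - stats.chi2.sf(x2, df=2))))


def combine_pair_confidence(
    chain_confidences: Sequence[float],
    used_haploblock: bool = False,
    placeholder: float = DEFAULT_HAPLOBLOCK_PLACEHOLDER,
) -> float:
    """c_comb: product of all per-step confidences along the phasing chain.

    Every read-level phasing test that contributed to the pair's constellation
    — including tests against and between bridging SNPs — enters the product.
    A haploblock link contributes the user-settable placeholder factor.
    """
    c = 1.0
    for value in chain_confidences:
        if not 0 <= value <= 1:
            raise ValueError(f"confidence {value} outside [0, 1]")
        c *= value
    if used_haploblock:
        if not 0 <= placeholder <= 1:
            raise ValueError(f"placeholder {placeholder} outside [0, 1]")
        c *= placeholder
    return c


def gene_confidence(
    status: str,
    pair_confidences: Mapping[tuple, float],
    decisive_evidence: str = "none",
) -> float:
    """Aggregate pairwise confidences into the gene-status confidence.

    Logic-decided genes (LOH single variant, homozygous deletion, compound
    pre-check flag) get 1.  ``all_copies_affected`` via phasing needs only
    the one decisive combination, so it inherits that pair's c_comb (the
    maximum over sufficient pairs is reported).  ``wt_copies_left`` via
    phasing needs *every* combination to leave wild-type copies, so it takes
    the product over all evaluated pairs.  ``undefined`` scores 0.
    """
    if decisive_evidence in _LOGIC_EVIDENCE:
        return 1.0
    if status == "undefined":
        return 0.0
    if status == "all_copies_affected":
        if not pair_confidences:
            return 1.0
        return max(pair_confidences.values())
    if status == "wt_copies_left":
        return math.prod(pair_confidences.values()) if pair_confidences else 1.0
    raise ValueError(f"unknown gene status {status!r}")


def aip_confidence(likelihoods: Iterable[float]) -> float:
    """Posterior probability of the chosen placement under a flat prior.

    The first entry is the likelihood of the chosen (maximum-likelihood)
    placement; the remainder are its competitors.  A single admissible
    placement yields 1.
    """
    values = list(likelihoods)
    if not values:
        raise ValueError("need at least one placement likelihood")
    if any(v < 0 for v in values):
        raise ValueError("likelihoods must be non-negative")
    total = sum(values)
    if total == 0:
        return 0.0
    return values[0] / total
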