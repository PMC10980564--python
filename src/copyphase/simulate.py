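"""Deterministic synthetic tumor/normal scenarios with known ground truth.

Each scenario is a tiny single-contig genome: a set of tumor genome copies
(each labelled with the parental allele it descends from), two normal
alleles, and SNVs placed on specific copies.  From this the module emits all
pipeline inputs as plain text — paired-end SAM, somatic and germline VCFs, a
phased-SNP VCF, the segment table and a gene BED — plus an analytic truth
table (per-variant affected copies, per-pair phase relation, per-gene
status).  Identical seeds yield byte-identical files.

Reads are drawn with uniform fragment starts from copies weighted by purity
(no GC or mappability bias) and fixed-size fragments; allele frequencies in
the emitted VCFs are the analytic mixture expectations, so the affected-copy
formulas invert them exactly.  The bundled scenario registry covers every
decision branch of the method: single variants with and without LOH in both
the somatic and germline case, homozygous deletions, the compound pre-check
flag, direct same/diff pairs, an indirect chain, a haploblock bridge, an
allelic-imbalance-only segment, a seven-event analog of a densely mutated
region whose two-diff chain must come out undefined, and a tetraploid gene.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

_BASES = "ACGT"
_ALT_OF = {"A": "C", "C": "G", "G": "T", "T": "A"}


@dataclass(frozen=True)
class SimVariant:
    """One placed SNV: on which tumor copies / normal alleles it sits."""

    vid: str
    pos: int  # 1-based
    origin: str  # somatic | germline
    tumor_copies: Tuple[int, ...]
    germline_allele: Optional[str] = None  # 'A' or 'B' for germline events
    is_snp: bool = False  # phased-SNP anchor, not a gene variant
    block_id: Optional[int] = None  # haploblock (phase set) of a SNP

    def __post_init__(self) -> None:
        if self.origin not in ("somatic", "germline"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.origin == "germline" and self.germline_allele not in ("A", "B"):
            raise ValueError("germline placements need an allele label")
        if self.is_snp and self.origin != "germline":
            raise ValueError("SNP anchors are germline by definition")


@dataclass
class Scenario:
    """A complete simulated study condition with its expected outcome."""

    name: str
    tumor_copies: Tuple[str, ...]  # parental allele label per tumor copy
    variants: List[SimVariant]
    expected_status: Optional[str]
    expected_pairs: Dict[Tuple[str, str], str] = field(default_factory=dict)
    purity: float = 0.8
    seed: int = 0
    contig: str = "chr1"
    length: int = 6000
    coverage: float = 80.0
    read_length: int = 100
    fragment_size: int = 250
    error_rate: float = 0.0
    normal_alleles: Tuple[str, ...] = ("A", "B")
    gene_id: str = "GENE1"
    gene_start: int = 1000  # 0-based half-open
    gene_end: int = 5000
    sex: str = "female"
    enable_aip: bool = False

    def __post_init__(self) -> None:
        labels = set(self.tumor_copies) | set(self.normal_alleles)
        if not labels <= {"A", "B"}:
            raise ValueError("allele labels are 'A' and 'B'")
        for v in self.variants:
            if any(c >= len(self.tumor_copies) for c in v.tumor_copies):
                raise ValueError(f"{v.vid}: placement outside the tumor copies")
            if v.origin == "germline":
                expect = tuple(
                    i for i, lab in enumerate(self.tumor_copies)
                    if lab == v.germline_allele
                )
                if tuple(sorted(v.tumor_copies)) != expect:
                    raise ValueError(
                        f"{v.vid}: germline tumor placement inconsistent with allele "
                        f"{v.germline_allele} and copies {self.tumor_copies}"
                    )

    # -- analytic mixture quantities ---------------------------------------
    @property
    def tcn(self) -> int:
        return len(self.tumor_copies)

    @property
    def cnorm(self) -> int:
        return len(self.normal_alleles)

    def normal_count(self, v: SimVariant) -> int:
        if v.origin == "somatic":
            return 0
        return sum(1 for a in self.normal_alleles if a == v.germline_allele)

    def true_ac(self, v: SimVariant) -> int:
        return len(v.tumor_copies)

    def expected_tumor_vaf(self, v: SimVariant) -> float:
        denom = self.purity * self.tcn + (1 - self.purity) * self.cnorm
        if denom == 0:
            return 0.0
        return (self.purity * self.true_ac(v) + (1 - self.purity) * self.normal_count(v)) / denom

    def expected_normal_vaf(self, v: SimVariant) -> float:
        return self.normal_count(v) / self.cnorm

    def true_relation(self, a: SimVariant, b: SimVariant) -> str:
        """Phase relation implied by the placements themselves.

        ``same`` when both events mark exactly the same copies, ``diff`` when
        their copy sets are disjoint; overlapping-but-unequal placements fit
        neither read pattern and are recorded as undefined.
        """
        sa, sb = set(a.tumor_copies), set(b.tumor_copies)
        if sa == sb and sa:
            return "same"
        if sa and sb and not (sa & sb):
            return "diff"
        return "undefined"

    def reference(self) -> str:
        rng = np.random.default_rng(self.seed)
        return "".join(rng.choice(list(_BASES), size=self.length))

    def alt_base(self, ref_base: str) -> str:
        return _ALT_OF[ref_base]

    def segment_row(self) -> dict:
        counts = {lab: self.tumor_copies.count(lab) for lab in ("A", "B")}
        cn_major, cn_minor = max(counts.values()), min(counts.values())
        return {
            "chrom": self.contig,
            "start": 0,
            "end": self.length,
            "tcn": self.tcn,
            "loh": self.tcn > 0 and cn_minor == 0,
            "homdel": self.tcn == 0,
            "cn_major": cn_major,
            "cn_minor": cn_minor,
            "haploblock_id": "hb1",
        }

    @property
    def gene_variants(self) -> List[SimVariant]:
        return [v for v in self.variants if not v.is_snp]

    @property
    def snps(self) -> List[SimVariant]:
        return [v for v in self.variants if v.is_snp]


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------


def _copy_sequences(scenario: Scenario) -> Tuple[List[str], List[str]]:
    """Per-copy sequences: (tumor copies, normal alleles) with SNVs applied."""
    ref = scenario.reference()

    def apply(seq: List[str], variants: Sequence[SimVariant]) -> str:
        out = list(seq)
        for v in variants:
            out[v.pos - 1] = scenario.alt_base(ref[v.pos - 1])
        return "".join(out)

    tumor = []
    for idx in range(scenario.tcn):
        carried = [v for v in scenario.variants if idx in v.tumor_copies]
        tumor.append(apply(list(ref), carried))
    normal = []
    for allele in scenario.normal_alleles:
        carried = [
            v for v in scenario.variants
            if v.origin == "germline" and v.germline_allele == allele
        ]
        normal.append(apply(list(ref), carried))
    return tumor, normal


_REVCOMP = str.maketrans("ACGT", "TGCA")


def emit_reads(scenario: Scenario) -> str:
    """Paired-end SAM text over the scenario's mixture genome.

    Fragment sources are the tumor copies (weight = purity each) and the
    normal alleles (weight = 1 - purity each); starts are uniform, fragment
    size fixed, base errors injected at ``error_rate`` with base qualities
    encoding exactly that error model.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    tumor, normal = _copy_sequences(scenario)
    sources = [(s, scenario.purity) for s in tumor] + [
        (s, 1.0 - scenario.purity) for s in normal
    ]
    sources = [(s, w) for s, w in sources if w > 0]
    header = (
        "@HD\tVN:1.6\tSO:coordinate\n"
        f"@SQ\tSN:{scenario.contig}\tLN:{scenario.length}\n"
        f"@RG\tID:sim\tSM:{scenario.name}\n"
    )
    if not sources:
        return header

    weights = np.array([w for _, w in sources], dtype=float)
    weights /= weights.sum()
    n_fragments = int(round(scenario.coverage * scenario.length / (2 * scenario.read_length)))
    rl, fs = scenario.read_length, scenario.fragment_size
    qual_phred = 60 if scenario.error_rate <= 0 else max(
        2, int(round(-10 * math.log10(scenario.error_rate)))
    )
    qual_str = chr(qual_phred + 33) * rl

    def with_errors(seq: str) -> str:
        if scenario.error_rate <= 0:
            return seq
        out = list(seq)
        hits = np.nonzero(rng.random(len(seq)) < scenario.error_rate)[0]
        for i in hits:
            out[i] = rng.choice([b for b in _BASES if b != out[i]])
        return "".join(out)

    records = []
    for i in range(n_fragments):
        src = rng.choice(len(sources), p=weights)
        start = int(rng.integers(0, scenario.length - fs + 1))
        frag = sources[src][0][start : start + fs]
        r1 = with_errors(frag[:rl])
        r2 = with_errors(frag[fs - rl :])
        name = f"frag{i:06d}"
        pos1, pos2 = start + 1, start + fs - rl + 1
        records.append(
            (pos1, f"{name}\t99\t{scenario.contig}\t{pos1}\t60\t{rl}M\t=\t{pos2}\t{fs}\t{r1}\t{qual_str}\tRG:Z:sim")
        )
        records.append(
            (pos2, f"{name}\t147\t{scenario.contig}\t{pos2}\t60\t{rl}M\t=\t{pos1}\t{-fs}\t{r2}\t{qual_str}\tRG:Z:sim")
        )
    records.sort(key=lambda r: (r[0], r[1]))
    return header + "\n".join(r[1] for r in records) + "\n"


def _vcf_header(scenario: Scenario, samples: Sequence[str]) -> str:
    cols = "\t".join(samples)
    return (
        "##fileformat=VCFv4.2\n"
        f"##contig=<ID={scenario.contig},length={scenario.length}>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">\n'
        '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n'
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n"
    )


def _sample_field(vaf: float, gt: str, depth: int = 100, ps: Optional[int] = None) -> str:
    alt = int(round(vaf * depth))
    base = f"{gt}:{depth - alt},{alt}:{depth}:{vaf:.6g}"
    return base + (f":{ps}" if ps is not None else "")


def emit_somatic_vcf(scenario: Scenario) -> str:
    ref = scenario.reference()
    lines = [_vcf_header(scenario, ["TUMOR"])]
    for v in sorted(scenario.gene_variants, key=lambda v: v.pos):
        if v.origin != "somatic":
            continue
        vaf = scenario.expected_tumor_vaf(v)
        rb = ref[v.pos - 1]
        lines.append(
            f"{scenario.contig}\t{v.pos}\t{v.vid}\t{rb}\t{scenario.alt_base(rb)}\t.\tPASS\t.\t"
            f"GT:AD:DP:AF\t{_sample_field(vaf, '0/1')}\n"
        )
    return "".join(lines)


def emit_germline_vcf(scenario: Scenario) -> str:
    ref = scenario.reference()
    lines = [_vcf_header(scenario, ["NORMAL", "TUMOR"])]
    for v in sorted(scenario.gene_variants, key=lambda v: v.pos):
        if v.origin != "germline":
            continue
        vaf_n = scenario.expected_normal_vaf(v)
        vaf_t = scenario.expected_tumor_vaf(v)
        gt_n = "1/1" if scenario.normal_count(v) == scenario.cnorm else "0/1"
        rb = ref[v.pos - 1]
        lines.append(
            f"{scenario.contig}\t{v.pos}\t{v.vid}\t{rb}\t{scenario.alt_base(rb)}\t.\tPASS\t.\t"
            f"GT:AD:DP:AF\t{_sample_field(vaf_n, gt_n)}\t{_sample_field(vaf_t, '0/1')}\n"
        )
    return "".join(lines)


def emit_phased_snp_vcf(scenario: Scenario) -> Optional[str]:
    """Phased het SNP anchors (haplotype 1 = parental allele A)."""
    snps = scenario.snps
    if not snps:
        return None
    ref = scenario.reference()
    lines = [_vcf_header(scenario, ["NORMAL"])]
    for v in sorted(snps, key=lambda v: v.pos):
        gt = "1|0" if v.germline_allele == "A" else "0|1"
        rb = ref[v.pos - 1]
        lines.append(
            f"{scenario.contig}\t{v.pos}\t{v.vid}\t{rb}\t{scenario.alt_base(rb)}\t.\tPASS\t.\t"
            f"GT:AD:DP:AF:PS\t{_sample_field(0.5, gt, ps=v.block_id or 1)}\n"
        )
    return "".join(lines)


def emit_segments(scenario: Scenario) -> str:
    row = scenario.segment_row()
    cols = ["chrom", "start", "end", "tcn", "loh", "homdel", "cn_major", "cn_minor", "haploblock_id"]
    values = [str(row[c]).lower() if isinstance(row[c], bool) else str(row[c]) for c in cols]
    return "\t".join(cols) + "\n" + "\t".join(values) + "\n"


def emit_gene_bed(scenario: Scenario) -> str:
    return f"{scenario.contig}\t{scenario.gene_start}\t{scenario.gene_end}\t{scenario.gene_id}\n"


def emit_truth(scenario: Scenario) -> Dict[str, pd.DataFrame]:
    """Analytic truth: per-variant ac, per-pair relations, per-gene status.

    ``expected_call`` is what a correct implementation should report given
    the scenario's read-length and bridging limits (e.g. undefined for a
    pair only reachable through two diff links); ``true_relation`` is the
    placement-level ground truth, which may be stricter.
    """
    gene_vars = sorted(scenario.gene_variants, key=lambda v: v.pos)
    variants = pd.DataFrame(
        [
            {
                "variant_id": v.vid,
                "origin": v.origin,
                "pos": v.pos,
                "true_ac": scenario.true_ac(v),
                "expected_tumor_vaf": scenario.expected_tumor_vaf(v),
            }
            for v in gene_vars
        ]
    )
    pair_rows = []
    for a, b in itertools.combinations(gene_vars, 2):
        key = (a.vid, b.vid)
        expected = scenario.expected_pairs.get(key) or scenario.expected_pairs.get(
            (b.vid, a.vid)
        )
        pair_rows.append(
            {
                "variant_a": a.vid,
                "variant_b": b.vid,
                "true_relation": scenario.true_relation(a, b),
                "expected_call": expected or "",
            }
        )
    pairs = pd.DataFrame(
        pair_rows, columns=["variant_a", "variant_b", "true_relation", "expected_call"]
    )
    gene = pd.DataFrame(
        [{"gene_id": scenario.gene_id, "expected_status": scenario.expected_status}]
    )
    return {"variants": variants, "pairs": pairs, "gene": gene}


def write_scenario(scenario: Scenario, out_dir: Path | str) -> Dict[str, Path]:
    """Write all scenario files; returns the path of each artifact."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sam": out / "tumor.sam",
        "somatic_vcf": out / "somatic.vcf",
        "germline_vcf": out / "germline.vcf",
        "segments": out / "segments.tsv",
        "genes": out / "genes.bed",
    }
    paths["sam"].write_text(emit_reads(scenario))
    paths["somatic_vcf"].write_text(emit_somatic_vcf(scenario))
    paths["germline_vcf"].write_text(emit_germline_vcf(scenario))
    paths["segments"].write_text(emit_segments(scenario))
    paths["genes"].write_text(emit_gene_bed(scenario))
    phased = emit_phased_snp_vcf(scenario)
    if phased is not None:
        paths["phased_vcf"] = out / "phased_snps.vcf"
        paths["phased_vcf"].write_text(phased)
    truth = emit_truth(scenario)
    for key, df in truth.items():
        p = out / f"truth_{key}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"truth_{key}"] = p
    return paths


# ---------------------------------------------------------------------------
# bundled scenarios — one per decision branch of the method
# ---------------------------------------------------------------------------


def _som(vid: str, pos: int, copies: Tuple[int, ...]) -> SimVariant:
    return SimVariant(vid=vid, pos=pos, origin="somatic", tumor_copies=copies)


def _germ(vid: str, pos: int, allele: str, tumor_copies: Tuple[str, ...]) -> SimVariant:
    placed = tuple(i for i, lab in enumerate(tumor_copies) if lab == allele)
    return SimVariant(
        vid=vid, pos=pos, origin="germline", tumor_copies=placed, germline_allele=allele
    )


def _snp(vid: str, pos: int, allele: str, tumor_copies: Tuple[str, ...], block: int) -> SimVariant:
    placed = tuple(i for i, lab in enumerate(tumor_copies) if lab == allele)
    return SimVariant(
        vid=vid, pos=pos, origin="germline", tumor_copies=placed,
        germline_allele=allele, is_snp=True, block_id=block,
    )


def _single_somatic_loh(seed: int) -> Scenario:
    copies = ("A",)
    return Scenario(
        name="single_somatic_loh",
        tumor_copies=copies,
        variants=[_som("m1", 3000, (0,))],
        expected_status="all_copies_affected",
        purity=1.0,
        seed=seed,
    )


def _single_somatic_no_loh(seed: int) -> Scenario:
    copies = ("A", "B")
    return Scenario(
        name="single_somatic_no_loh",
        tumor_copies=copies,
        variants=[_som("m1", 3000, (0,))],
        expected_status="wt_copies_left",
        seed=seed,
    )


def _single_germline_loh_retained(seed: int) -> Scenario:
    copies = ("A",)
    return Scenario(
        name="single_germline_loh_retained",
        tumor_copies=copies,
        variants=[_germ("g1", 3000, "A", copies)],
        expected_status="all_copies_affected",
        seed=seed,
    )


def _single_germline_loh_lost(seed: int) -> Scenario:
    copies = ("A",)
    return Scenario(
        name="single_germline_loh_lost",
        tumor_copies=copies,
        variants=[_germ("g1", 3000, "B", copies)],
        expected_status="wt_copies_left",
        seed=seed,
    )


def _homdel(seed: int) -> Scenario:
    return Scenario(
        name="homdel",
        tumor_copies=(),
        variants=[],
        expected_status="all_copies_affected",
        seed=seed,
    )


def _precheck_flag(seed: int) -> Scenario:
    copies = ("A", "A", "B", "B")
    return Scenario(
        name="precheck_flag",
        tumor_copies=copies,
        variants=[_som("m1", 2000, (0,)), _som("m2", 2150, (2,))],
        expected_status="wt_copies_left",
        expected_pairs={},  # phasing intentionally skipped
        seed=seed,
    )


def _direct_same(seed: int) -> Scenario:
    copies = ("A", "B")
    return Scenario(
        name="direct_same",
        tumor_copies=copies,
        variants=[_som("m1", 2000, (0,)), _som("m2", 2150, (0,))],
        expected_status="wt_copies_left",
        expected_pairs={("m1", "m2"): "same"},
        seed=seed,
    )


def _direct_diff(seed: int) -> Scenario:
    copies = ("A", "B")
    return Scenario(
        name="direct_diff",
        tumor_copies=copies,
        variants=[_som("m1", 2000, (0,)), _som("m2", 2150, (1,))],
        expected_status="all_copies_affected",
        expected_pairs={("m1", "m2"): "diff"},
        seed=seed,
    )


def _indirect_chain(seed: int) -> Scenario:
    # m1-m2 and m2-m3 are bridgeable by one fragment; m1-m3 (300 bp apart,
    # beyond the 250 bp fragment) must be imputed: same + diff -> diff.
    copies = ("A", "B")
    return Scenario(
        name="indirect_chain",
        tumor_copies=copies,
        variants=[_som("m1", 2000, (0,)), _som("m2", 2150, (0,)), _som("m3", 2300, (1,))],
        expected_status="all_copies_affected",
        expected_pairs={
            ("m1", "m2"): "same",
            ("m2", "m3"): "diff",
            ("m1", "m3"): "diff",
        },
        seed=seed,
    )


def _two_diff_undefined(seed: int) -> Scenario:
    # The densely mutated-region analog: adjacent pairs resolve directly, but
    # any inference across two diff links (m2-m4, m1-m4) stays undefined.
    copies = ("A", "B")
    return Scenario(
        name="two_diff_undefined",
        tumor_copies=copies,
        variants=[
            _som("m1", 2000, (0,)),
            _som("m2", 2150, (0,)),
            _som("m3", 2300, (1,)),
            _som("m4", 2450, (0,)),
        ],
        expected_status="all_copies_affected",  # decided by the direct m2-m3 diff pair
        expected_pairs={
            ("m1", "m2"): "same",
            ("m2", "m3"): "diff",
            ("m3", "m4"): "diff",
            ("m1", "m3"): "diff",
            ("m2", "m4"): "undefined",
            ("m1", "m4"): "undefined",
        },
        seed=seed,
    )


def _haploblock_bridge(seed: int) -> Scenario:
    # m1 and m2 are 3 kb apart; each anchors to a phased SNP of block 1.
    copies = ("A", "B")
    return Scenario(
        name="haploblock_bridge",
        tumor_copies=copies,
        variants=[
            _som("m1", 1500, (0,)),
            _som("m2", 4500, (1,)),
            _snp("s1", 1650, "A", copies, block=1),
            _snp("s2", 4350, "A", copies, block=1),
        ],
        expected_status="all_copies_affected",
        expected_pairs={("m1", "m2"): "diff"},
        seed=seed,
    )


def _aip_only(seed: int) -> Scenario:
    # 2+1 allelic imbalance; the germline variants are too far apart for any
    # read-level route and resolve only by allelic-imbalance genotyping.
    copies = ("A", "A", "B")
    return Scenario(
        name="aip_only",
        tumor_copies=copies,
        variants=[_germ("g1", 2000, "A", copies), _germ("g2", 3500, "B", copies)],
        expected_status="all_copies_affected",
        expected_pairs={("g1", "g2"): "diff"},
        enable_aip=True,
        seed=seed,
    )


def _ploidy4_diff(seed: int) -> Scenario:
    copies = ("A", "A", "B", "B")
    return Scenario(
        name="ploidy4_diff",
        tumor_copies=copies,
        variants=[_germ("g1", 2000, "A", copies), _germ("g2", 2150, "B", copies)],
        expected_status="all_copies_affected",
        expected_pairs={("g1", "g2"): "diff"},
        seed=seed,
    )


SCENARIOS: Dict[str, Callable[[int], Scenario]] = {
    "single_somatic_loh": _single_somatic_loh,
    "single_somatic_no_loh": _single_somatic_no_loh,
    "single_germline_loh_retained": _single_germline_loh_retained,
    "single_germline_loh_lost": _single_germline_loh_lost,
    "homdel": _homdel,
    "precheck_flag": _precheck_flag,
    "direct_same": _direct_same,
    "direct_diff": _direct_diff,
    "indirect_chain": _indirect_chain,
    "two_diff_undefined": _two_diff_undefined,
    "haploblock_bridge": _haploblock_bridge,
    "aip_only": _aip_only,
    "ploidy4_diff": _ploidy4_diff,
}


def build(name: str, seed: int = 0) -> Scenario:
    try:
        factory = SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(SCENARIOS))}"
        ) from None
    return factory(seed)
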