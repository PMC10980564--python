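"""Shared fixtures: handcrafted alignments and cached scenario pipeline runs."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Tuple

import pysam
import pytest
from hypothesis import settings

from copyphase import simulate as sim
from copyphase.pipeline import RunConfig, run_pipeline

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def sam_to_bam(sam_text: str, workdir: Path, stem: str = "reads") -> Path:
    """Materialize SAM text as a coordinate-sorted, indexed BAM."""
    sam_path = workdir / f"{stem}.sam"
    bam_path = workdir / f"{stem}.bam"
    sam_path.write_text(sam_text)
    pysam.sort("-o", str(bam_path), str(sam_path))
    pysam.index(str(bam_path))
    return bam_path


# 50 bp toy reference used by the handcrafted read fixtures; the two SNVs are
# pos 10 A>C and pos 30 G>T (1-based).
TOY_REF = "ACGTACGTA" + "A" + "C" * 19 + "G" + "ACGTACGTACGTACGTACGT"


def _toy_read(name, flag, pos, seq, mapq=60, cigar=None, qual_char="I",
              rnext="*", pnext=0, tlen=0):
    cigar = cigar or f"{len(seq)}M"
    qual = qual_char * len(seq)
    return (
        f"{name}\t{flag}\tchrT\t{pos}\t{mapq}\t{cigar}\t{rnext}\t{pnext}\t{tlen}"
        f"\t{seq}\t{qual}"
    )


def toy_pair_sam() -> str:
    """Six informative fragments over the SNV pair (pos 10, pos 30).

    Expected classification (manual pileup): one ``both``, one ``mut1``, one
    ``mut2``, one ``none``, one mate-pair ``both`` (each mate covering one
    position), plus a low-baseq and a low-mapq fragment that must be ignored.
    """
    ref = TOY_REF

    def window(start1, end1, subs: Dict[int, str]) -> str:
        out = list(ref[start1 - 1 : end1])
        for pos1, base in subs.items():
            out[pos1 - start1] = base
        return "".join(out)

    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        "@SQ\tSN:chrT\tLN:50",
        _toy_read("r_both", 0, 5, window(5, 35, {10: "C", 30: "T"})),
        _toy_read("r_mut1", 0, 5, window(5, 35, {10: "C"})),
        _toy_read("r_mut2", 0, 5, window(5, 35, {30: "T"})),
        _toy_read("r_none", 0, 5, window(5, 35, {})),
        _toy_read("p_both", 99, 5, window(5, 20, {10: "C"}),
                  rnext="=", pnext=25, tlen=36),
        _toy_read("p_both", 147, 25, window(25, 40, {30: "T"}),
                  rnext="=", pnext=5, tlen=-36),
        _toy_read("r_lowq", 0, 5, window(5, 35, {10: "C", 30: "T"}), qual_char="&"),
        _toy_read("r_lowmapq", 0, 5, window(5, 35, {10: "C", 30: "T"}), mapq=5),
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def toy_bam(tmp_path_factory) -> Path:
    return sam_to_bam(toy_pair_sam(), tmp_path_factory.mktemp("toy"), "toy")


@pytest.fixture(scope="session")
def run_scenario(tmp_path_factory):
    """Factory: run the full pipeline on a bundled scenario, cached per (name, seed)."""
    cache: Dict[Tuple[str, int], tuple] = {}

    def runner(name: str, seed: int = 7):
        key = (name, seed)
        if key not in cache:
            scenario = sim.build(name, seed)
            out = tmp_path_factory.mktemp(f"scen_{name}")
            paths = sim.write_scenario(scenario, out)
            cfg = RunConfig(
                somatic_vcf=paths["somatic_vcf"],
                germline_vcf=paths["germline_vcf"],
                segments_tsv=paths["segments"],
                genes_path=paths["genes"],
                dna_bam=paths["sam"],
                phased_snp_vcf=paths.get("phased_vcf"),
                purity=scenario.purity,
                sex=scenario.sex,
                enable_aip=scenario.enable_aip,
                out_dir=out / "results",
            )
            cache[key] = (scenario, run_pipeline(cfg), paths)
        return cache[key]

    return runner
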