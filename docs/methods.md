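# Methods

This note documents the model implemented by `copyphase`, the parameters
that matter, the numerical conventions, and what the synthetic scenarios do
and do not establish.

## Model and assumptions

A bulk tumor sample is modelled as a two-component mixture: a fraction `p`
(purity) of clonal tumor cells carrying `c_tum` copies of a locus, and
`1 - p` normal cells carrying `c_norm` copies (2 on autosomes and on female
X, 1 on male X and on Y). Every allele-frequency-derived quantity assumes a
cancer cell fraction of 1 — subclonality is explicitly out of scope, and
violations show up as affected-copy estimates outside the physical range
(see *Clamping*).

**Affected copies.** The observed VAF of a somatic variant is the fraction
of reads coming from the variant-bearing tumor copies out of all copies in
the mixture; solving for the number of variant-bearing copies gives
`ac_som = VAF_tum * (c_tum + c_norm*(1/p - 1))`. Germline variants also
contribute reads from normal cells, which the control VAF subtracts:
`ac_germ = VAF_tum*c_tum + (VAF_tum - VAF_norm)*c_norm*(1/p - 1)`. When the
control VAF is unobserved it defaults to 0.5 (heterozygous, diploid locus)
or 1 (homozygous genotype, or hemizygous male X/Y locus), with the genotype
hint taken from the germline VCF GT field.

**Gene status.** Evaluation order per gene: (1) homozygous deletion
overlapping the gene → `all_copies_affected`; (2) single variants: under
LOH, a somatic variant is decisive when `c_tum - ac < 0.5` remaining
wild-type copies, a germline variant when its tumor VAF exceeds 0.5;
without LOH a lone small variant never reaches the second allele; (3) the
compound pre-check: if even the all-different-copies assumption leaves every
pair ≥ 0.5 wild-type copies, the gene is flagged and phasing is skipped;
(4) phased pairs: integrated affected copies `max(ac1, ac2)` (same copy) or
`ac1 + ac2` (different copies), decisive below 0.5 remaining wild-type
copies; (5) all decisive pairs resolved and none sufficient →
`wt_copies_left`; (6) otherwise `undefined`.

**Phasing.** Fragments (reads, or mate pairs sharing a name) covering both
positions of a pair are classified *both*/*mut1*/*mut2*/*none* by CIGAR-aware
allele extraction. The strict patterns decide the constellation: *same*
requires at least one *both* and zero contradicting single-variant weight,
*diff* the inverse. Unresolved pairs are chained through bridging events
(other variants, nearby phased SNPs) and through haploblock links between
SNPs of one phase set; a chain's relation depends only on its number of
*diff* links — 0 → same, 1 → diff, and ≥ 2 → undefined, because two
different-copy steps can no longer exclude the involvement of additional
copies at ploidy > 2.

**Anchoring to germline SNPs.** The strict pair patterns cannot hold when
one member of the pair is a heterozygous SNP: admixed normal cells (and
tumor copies without the somatic variant) legitimately produce SNP-only
fragments. Anchoring therefore conditions on the fragments that carry the
*variant*: if they all carry the SNP's alternative allele too, the variant
sits on that haplotype; if none do, on the other. This is the package's own
resolution of a case the strict patterns leave unreachable, and it is what
makes haploblock bridging work at purity < 1.

**Allelic-imbalance phasing (AIP).** In segments with `cn_major ≠ cn_minor`
a variant's VAF hints at its allele of origin. Candidate placements carry
`k` copies — germline: `k = cn_major` or `cn_minor` (plus one normal copy in
the mixture); somatic: additionally the post-CNA placement `k = 1` with no
normal contribution — each with expected VAF
`(p*k + (1-p)*g) / (p*c_tum + (1-p)*c_norm)` (`g` = normal-copy count). The
observed VAF, discretized at a nominal depth (default 100), is scored with a
binomial likelihood; the maximum-likelihood allele is accepted only when it
beats the best other-allele placement by a likelihood ratio (default 10).
The somatic post-CNA placement is allele-ambiguous by construction, so a
somatic variant whose best explanation is (or ties with) the timing-ambiguous
one stays undefined. AIP is genuinely low-confidence — the order of
copy-number and point-mutation events is unknown — and is disabled unless
explicitly enabled. The binomial construction and its flat-prior posterior
confidence are this package's own concrete choice for an approach the method
describes only at the level of genotype likelihoods.

## Confidence

All scores live in [0, 1]. Per read:
`c_rc = (1-p_bc,1)(1-p_mq,1)(1-p_bc,2)(1-p_mq,2)` with basecall and mapping
error probabilities from the Phred-scaled qualities (`p = 10^(-Q/10)`).
Per pair: the `c_rc`-weighted category counts over {both, mut1, mut2} are
compared against the counts expected under the **opposite** constellation
with `X² = Σ (obs - exp)²/(exp + ε)` and scored as `1 - P(χ²₂ > X²)`, so
evidence far from the alternative scores near 1. This is an empirical
measure inspired by the chi-square test, not a calibrated probability; the
pseudocount `ε = 0.5`, the 2 degrees of freedom, and the
evaluate-the-alternative convention are this implementation's fixed choices
for a statistic the method leaves open, and they are pinned by their own
oracle tests. *none* reads are consistent with either constellation whenever
a wild-type copy exists and are excluded from the statistic. Chain products
give the pair confidence `c_comb`; haploblock links contribute a
user-settable placeholder factor (default 1.0, logged at startup) because
the upstream haploblock caller's accuracy is unknown to this package.
Per gene: logic-decided verdicts (LOH single variant, homozygous deletion,
pre-check flag) get 1; `all_copies_affected` via phasing inherits the
decisive pair's `c_comb` (one sufficient combination decides);
`wt_copies_left` via phasing takes the product over all evaluated pairs
(every combination is required); `undefined` gets 0.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `purity` | required | tumor cell fraction in (0, 1] |
| `min_baseq` / `min_mapq` | 20 / 30 | Phred cutoffs; sub-cutoff support drops the fragment |
| `noise_tolerance` (τ) | 0.0 | weighted contradicting-read tolerance in the same/diff patterns; 0 is the literal rule |
| `haploblock_placeholder` | 1.0 | confidence factor per haploblock link |
| `max_chain_length` | 6 | bound on inference-chain edges (cost control) |
| `enable_aip` | off | expert opt-in for allelic-imbalance phasing |
| `aip_depth` / `aip_lr_threshold` | 100 / 10 | binomial discretization depth; required likelihood ratio |
| `snp_window` | 10 kb | how far beyond the gene to collect SNP anchors |
| `par_intervals` | none | user-supplied pseudoautosomal intervals restoring `c_norm = 2` on male X/Y |

## Numerical conventions and degenerate inputs

- Coordinates: VCF positions 1-based; all intervals 0-based half-open.
  Contig names are prefix-normalized (`chr1` ≡ `1`).
- Thresholds are strict: exactly 0.5 remaining wild-type copies is
  `wt_copies_left`; a germline tumor VAF of exactly 0.5 under LOH decides
  neither direction and yields `undefined`.
- Clamping: `ac > c_tum` is clamped to `c_tum`, `ac < 0` to 0, both flagged
  and logged — they signal noise or a violated clonality assumption rather
  than an input error.
- Fractional segment copy numbers are used as-is; no rounding.
- A Y contig is treated as haploid regardless of stated sex (it exists in
  one copy whenever it is present at all).
- Variants in regions uncovered by any segment are excluded with a warning,
  not fatal. Variant pairs spanning segments of different copy number are
  evaluated at the minimum of the two, logged.
- Mates disagreeing at a variant position make the fragment `none`
  (uninterpretable); spliced RNA gaps (`N`) count as uncovered, not deleted.
- Path search ties (equal confidence) break by shorter chain, then
  lexicographic node order. Chains never compose an undefined link. A cycle
  contradicting a directly observed relation keeps the direct call, is
  logged, and poisons imputations through its edges to `undefined`.
- Multi-allelic VCF records split per alt; FILTER-failing records are
  excluded by default. VAF precedence: FORMAT/AF, then alt-AD/DP, then
  INFO/AF. A germline VCF without a tumor sample gets its tumor VAFs from a
  pileup over the DNA alignments.

## Synthetic scenarios

The generator (`copyphase.simulate`) builds single-contig mixtures from
explicit copy placements: tumor copies labelled by parental allele, two
normal alleles, SNVs placed on specific copies. Emitted VAFs are the
analytic mixture expectations, so the affected-copy formulas invert them to
the true integer placements exactly; reads are drawn uniformly (fixed
fragment size 250 bp, read length 100 bp, default coverage 80×, purity 0.8
unless a scenario pins it) with byte-identical output per seed. The thirteen
bundled scenarios cover each decision branch: single variants with and
without LOH (somatic and germline, both loss directions), homozygous
deletion, the pre-check flag, direct same/diff pairs, an indirect chain, a
haploblock bridge, an allelic-imbalance-only pair, a tetraploid diff pair,
and a densely mutated analog whose two-diff chain must leave the distant
pair undefined. Problem sizes (6 kb contig, ~2 400 fragments per scenario)
were chosen so a scenario exercises every code path with unambiguous
analytic truth while a full suite run stays in the tens of seconds.

What passing these scenarios does **not** show: robustness to sequencing
error and mapping artefacts (reads are error-free by default; qualities
encode the injected error model when one is set), GC/mappability coverage
bias, Indel realignment effects (the generator places SNVs only — the Indel
extraction path is exercised by handcrafted alignments in the unit tests),
RNA splice structure (RNA support is tested on constructed evidence, not
simulated transcripts), subclonal architecture, or miscalled copy-number
input. On real data the confidence values depend on upstream callers in
ways no simulation here measures.

## Known limitations

- Clonality is assumed, not checked; heavily subclonal samples will clamp
  often and the flags should be taken seriously.
- Phasing is pairwise; three-way joint constellations are never constructed,
  so a gene needing a genuinely higher-order argument stays conservative.
- The AIP genotype model is a deliberate simplification (binomial at a
  nominal depth) and is off by default.
- Structural variants, fusions, and epigenetic inactivation are outside the
  model: a gene can be functionally dead with `wt_copies_left`.
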