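# copyphase

Gene-level zygosity of small variants in clonal tumor samples.

In precision oncology it often matters less *that* a gene is mutated than
*how many copies* of it are: a tumor-suppressor with one intact allele left
behaves very differently from one with none. `copyphase` takes the outputs a
tumor sequencing pipeline already produces — somatic and germline small
variant calls (VCF), allele-specific somatic copy-number segments, tumor
purity, sample sex, gene intervals and the aligned tumor reads — and decides,
per gene, whether **all copies are affected**, **wild-type copies are left**,
or the evidence is **undefined**, each with a confidence value in [0, 1].

## The model

For a variant in a segment of tumor copy number $c_{tum}$, with expected
normal copy number $c_{norm}$ (2 on autosomes and female X, 1 on male X/Y)
and tumor purity $p$, the number of tumor copies carrying the variant
(*affected copies*, $ac$) follows from inverting the read-mixture that
produced the observed allele frequencies:

$$ac_{som} = \mathrm{VAF}_{tum} \cdot \left(c_{tum} + c_{norm}\left(\tfrac{1}{p} - 1\right)\right)$$

$$ac_{germ} = \mathrm{VAF}_{tum} \cdot c_{tum} + (\mathrm{VAF}_{tum} - \mathrm{VAF}_{norm}) \cdot c_{norm}\left(\tfrac{1}{p} - 1\right)$$

A single variant can only exhaust a gene's copies under loss of
heterozygosity (LOH): a somatic variant when $c_{tum} - ac < 0.5$ remaining
wild-type copies, a germline variant when its tumor VAF exceeds 0.5 (the
wild-type allele was the one lost). A homozygous deletion always affects all
copies. With several variants in one gene, the pair's phase relation
(*constellation*) converts per-variant $ac$ into *integrated affected
copies*: $\max(ac_1, ac_2)$ if both sit on the same copy, $ac_1 + ac_2$ if
on different copies, again compared against the 0.5 wild-type-copy bound.

Constellations are called from sequencing fragments that cover both variant
positions (categories *both* / *mut1* / *mut2* / *none*), with fallbacks
through bridging variants and SNPs, phased haploblocks (PS tags), and —
strictly opt-in — allelic-imbalance genotyping. Chains of inferences that
pass through two or more *different-copy* links cannot exclude extra copies
and stay undefined. Every phasing step carries a confidence (each read
weighted by its basecall/mapping quality product, pairs scored with a
chi-square-inspired statistic against the opposite constellation), and a
gene's confidence is the product of the steps its verdict needed;
logic-decided genes (LOH, homozygous deletion, or the compound pre-check)
get confidence 1. The model assumes a clonal tumor (cancer cell fraction 1).

## Worked example

The package ships a deterministic scenario generator, so a complete run
needs no external data. Two somatic variants on different copies of a
diploid gene (purity 0.8):

```bash
copyphase simulate --scenario direct_diff --seed 3 --out demo
copyphase run \
    --somatic-vcf demo/somatic.vcf --germline-vcf demo/germline.vcf \
    --segments demo/segments.tsv --genes demo/genes.bed \
    --dna-bam demo/tumor.sam --purity 0.8 --sex female --out demo/results
```

`demo/results/genes.tsv`:

```
gene_id	status	confidence	iac	wt_copies_remaining	decisive_evidence	n_variants	flagged
GENE1	all_copies_affected	1	2	0	phased_pair	2	False
```

`demo/results/pairs.tsv`:

```
gene_id	variant_a	variant_b	relation	confidence	method	chain
GENE1	m1	m2	diff	1	direct	m1->m2
```

Each variant has allele frequency 0.222, which at purity 0.8 and copy
number 2 inverts to exactly 1.0 affected copy apiece (`demo/results/variants.tsv`).
Read-level phasing finds fragments carrying each variant alone and none
carrying both, so the pair is on *different* copies: integrated affected
copies 1 + 1 = 2 exhausts both copies (0 wild-type copies remain, below the
0.5 bound) and the gene is called `all_copies_affected`. The confidence
rounds to 1 because the simulated reads are error-free.

The same `copyphase run` command works on real pipeline outputs; `copyphase
phase` stops after the pair table, and the library API
(`copyphase.run_pipeline`, or the per-step functions) exposes every stage.

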