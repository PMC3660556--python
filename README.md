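# melexo

Exome characterization of small tumor cell-line cohorts: a tested,
reusable implementation of the whole-exome SNV analysis used to profile
panels of metastatic melanoma cell lines — high-quality SNV selection,
read-depth calibration against SNP-array genotypes, mutation-spectrum and
NS/S statistics, cancer-catalogue and curated-list screening, gene-level
copy-number calls and a de-novo recurrent-gene screen — together with a
fully seeded synthetic cohort generator with ground truth.

## Who this is for

Groups characterizing a handful of tumor samples or cell lines by
whole-exome sequencing plus SNP arrays, who need the downstream analysis
(after alignment and variant calling) to be reproducible, auditable and
testable. Raw-data steps (alignment, duplicate marking, recalibration,
variant calling, array segmentation) are upstream and out of scope: the
pipeline consumes VCFs, array genotype calls and copy-number segments.

## The analysis

**HQ-SNV filter.** Per-sample SNV calls are reduced to novel coding
high-quality SNVs by a cascade: remove known polymorphisms, non-coding
positions, blacklisted regions (HLA loci, homologous repeats) and variants
seen in prior in-house projects, then require read depth ≥ 15, call quality
> 150 and non-reference allele fraction (AF) > 0.20. Survivors are
classified heterozygous (AF ≈ 0.5) or homozygous (AF ≈ 1; cutoff AF ≥ 0.85).

**Depth calibration.** The depth threshold is grounded in WES-vs-array
genotype concordance: stratified by array genotype, homozygous strata stay
near 100% at any depth while the heterozygous stratum climbs with depth.
Under binomial sampling of alleles at a het site covered by *d* reads, a
caller that only miscalls all-ref/all-alt read vectors has expected het
concordance 1 − 2·(½)^d. The selected minimum depth is the smallest *d*
whose het concordance sustains the target level (default 90%) at all higher
depths.

**Spectrum and NS/S.** Substitutions are collapsed with their reverse
complements into 6 classes; C>T/G>A dominance is the UV signature of
cutaneous melanoma. The NS/S ratio (missense + nonsense over synonymous)
near 2 is the expectation for unselected passengers; strong excess within a
gene class suggests selection.

**Screens.** Variants are confirmed against a COSMIC-style catalogue by
exact genomic position (and allele identity, by default); curated
melanoma-related genes are grouped by signalling cascade or molecular
function with per-class NS/S counts; genes with non-synonymous mutations in
≥ 2 samples that are absent from both the catalogue and the curated list
are reported as "de novo" recurrent genes.

**Copy number.** Segments with CN > 2.3 are amplifications and CN < 1.3
deletions (CN < 0.7: two-copy/homozygous deletion). A gene is called
deleted only when merged deletion segments span its entire locus; a
non-synonymous mutation plus one-copy loss of the same gene in the same
sample is reported as a compound (two-hit) event.

## Worked example

```
melexo simulate --seed 42 --out demo/cohort
melexo run --input-dir demo/cohort --out demo/report --seed 42
```

prints

```
wrote cohort for 6 samples to demo/cohort
HQ-SNVs: 364 (NS 237 / S 127, NS/S 1.87)
report written to demo/report
```

The simulated cohort holds six samples of 5,000 SNV calls each with the
structure the analysis assumes (UV-dominated spectrum, ~8% novel variants,
negative-binomial depths around 45x, a BRAF V600E-like driver in four
samples and an NRAS Q61R-like driver in one, CDKN2A homozygous deletions).
Of ~30,000 calls, 364 survive the cascade — novel, coding, well-supported —
and the cohort NS/S of 1.87 sits where passenger-dominated exomes are
expected to sit. `demo/report/summary.tsv` starts

```
sample_id  n_total_snvs  n_novel  n_novel_coding  n_hq  n_nonsynonymous  n_synonymous  ns_s_ratio
Me01       5000          426      81              60    41               19            2.16
Me02       5001          433      82              57    40               17            2.35
```

and `report.json` carries the run's headline scalars, e.g. the injected
drivers confirmed against the catalogue (`n_confirmed_catalogue_genes: 2` —
BRAF and NRAS) and the homozygous-deletion genes recovered from the CN
segments. `manifest.json` pins config, input checksums and per-stage
attrition so a re-run is byte-identical.

The same stages are available as library functions
(`melexo.apply_hq_filter`, `melexo.concordance_by_depth`,
`melexo.match_catalogue`, `melexo.call_genes`, ...) and as per-stage CLI
subcommands (`melexo filter`, `melexo concordance`).

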