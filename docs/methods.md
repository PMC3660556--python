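# Methods

## Scope and data model

The pipeline starts where variant calling ends. Its unit of analysis is the
`SnvRecord`: one biallelic single-nucleotide variant call with read depth,
call quality, non-reference allele fraction (AF) and annotation flags.
Copy-number segments are consumed as continuous per-sample CN values
(`CnSegment`); array genotypes (`ArrayGenotype`) are three-valued calls
treated as a gold standard; catalogues are exact-position mutation lists.
All coordinates are 1-based inclusive internally (the VCF convention, since
variants are the central object); BED inputs are converted at the boundary,
and the conversion is tested to be an identity round-trip.

AF is defined as non-reference reads over all reads at the site. When
FORMAT/AD is present the reader recomputes AF from allelic depths rather
than trusting a pre-computed field — the recomputation is unambiguous and
round-trips exactly through the writer, which encodes AF back into integer
allelic depths. Multi-allelic lines are split into biallelic records because
every downstream predicate is per-allele.

## The HQ-SNV cascade

Stages, in fixed reporting order: known → coding → blacklist → in-house →
depth → quality → AF. Each stage is an independent per-variant predicate, so
the survivor set is provably order-independent (the suite checks the cascade
against a brute-force conjunction on randomized inputs); the order matters
only for attrition accounting. Threshold semantics are read literally from
their phrasing: *minimum* depth 15 is inclusive (≥ 15), quality *above* 150
and AF *above* 20% are strict. Coding status comes from the annotated
consequence when present; unannotated variants fall back to a positional
CDS-overlap query (interval tree, inclusive ends). Positions in introns or
UTRs are non-coding.

Zygosity uses a single cutoff — homozygous iff AF ≥ 0.85 (configurable) —
rather than the idealized point values 0.5 and 1, because observed fractions
are binomially noisy; equality tests on real AFs would be vacuous. 0.85 is
roughly the midpoint beyond which a 0.5-centred binomial at calling depths
is unlikely, and it doubles as the hom-call boundary of the concordance
genotype caller for consistency.

## Depth calibration against array genotypes

WES genotypes at array sites are derived from AF with a threshold caller
(hom-ref ≤ min_af, hom-alt ≥ hom_af_cutoff, het between). VCFs omit
reference calls, so hom-ref WES evidence at uncovered-by-variant array sites
is taken from a depth-per-site table; depth alone suffices because a site
with coverage and no call is a reference call. Which genotype caller the
original comparison used is not derivable from the analysis description;
the AF-threshold caller is declared here as this package's choice.

Concordance is binned at integer depths 1..50 (depths above 50 clamp into
the last bin); bins with fewer than 25 sites are reported as undefined —
NaN, never zero — so noisy tails cannot drive threshold selection. The
"plateau" is operationalized as a *sustained* crossing: the selected depth
is the smallest whose het concordance meets the level at that bin and every
defined bin above it. A brute-force suffix scan is kept in the tests as the
oracle. Under binomial allele sampling with the naive caller (miscall only
on all-ref or all-alt read vectors), het concordance has the closed form
1 − 2·(½)^d, which the suite verifies by exhaustive enumeration at depth 4
and by Monte Carlo at 10,000 sites per bin (3 SE).

## Spectrum and NS/S

The six collapsed substitution classes are keyed by the pyrimidine-reference
member and displayed with both members ("C>T/G>A"). Class counts always sum
to the variant count, and the spectrum is invariant under complementing
every variant's alleles (randomized property test). Whole-dataset and
per-sample NS/S ratios are rounded to two decimals and functional-class
ratios to one, matching conventional reporting precision; a zero synonymous
count yields an explicit undefined marker, not infinity. Cohort means are
reported rounded to integers.

## Screens

Catalogue confirmation requires exact chromosome+position match and, by
default, allele identity — position-only matching is available but inflates
confirmations. When several catalogue entries share a key the first under a
documented sort (chrom, pos, gene, ref, alt) wins, and each variant matches
at most one entry. Special states: truncating iff nonsense; homozygous iff
the zygosity call is homozygous; double-mutated iff the (gene, sample) pair
carries ≥ 2 distinct non-synonymous variants. A gene listed under several
functional classes contributes its variants to each class; synonymous
variants of member genes are included in the class S count. Recurrence rows
need non-synonymous variants in ≥ 2 distinct samples (configurable) and the
de-novo screen removes genes present in either the cancer catalogue or the
curated list; output disjointness is asserted exhaustively. Carrier
percentages are floor-rounded (4/6 → 66%). Mutual exclusivity between two
genes is computed as the exact intersection of carrier sample sets.

## Gene-level copy number

Segment classes partition by thresholds: amplified iff CN > 2.3, deletion
iff CN < 1.3 (both strict), neutral otherwise; a deletion with CN < 0.7 is a
two-copy (homozygous) loss. The 2.3/1.3 boundaries are the published
operating points; **the one- vs two-copy boundary is not printed anywhere
upstream**, so hd_cn = 0.7 is this package's own constant, placed
symmetrically between CN ≈ 1 and CN ≈ 0 and exposed in the config. Gene
calls apply an entire-locus rule: deleted (or amplified — the same rule is
applied to amplifications for symmetry) only when merged runs of same-class
segments contain the whole locus. Adjacent same-class segments are merged
before the containment test because segmentation breakpoints are arbitrary;
the run's minimum CN decides one- vs two-copy loss. Any partial overlap is
its own status and never a deletion — the suite includes a metamorphic test
that shrinking a covering deletion always demotes the call. Compound events
join non-synonymous HQ-SNVs with one-copy-loss calls per (sample, gene).

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes, as fixed
defaults: 6 samples × 5,000 SNV calls; collapsed-class weights
(0.60, 0.10, 0.08, 0.12, 0.05, 0.05) putting C>T/G>A dominance in the
observed 45–69% band; novel fraction 0.08 (known polymorphisms dominate raw
calls); coding fraction 0.20 of calls in CDS; het fraction 0.80; depths
negative-binomial with mean 45 and dispersion 8 (the 45x mean on-target
depth as a scale anchor); call qualities Gamma(4, 60), leaving roughly a
quarter of calls below the 150 cutoff; AF from binomial sampling of reads at
het sites plus Gaussian read-count jitter (sd 0.02·depth), quantized to the
allelic-depth grid so files round-trip exactly. Consequences
(synonymous/missense/nonsense at 0.34/0.62/0.04, NS/S ≈ 1.9) are assigned
labels, not computed from codons — the pipeline consumes annotation, and a
codon engine is out of scope. Known/in-house status is drawn once per
distinct site, not per sample-variant, mirroring positional catalogues and
keeping flags consistent across samples.

The gene model is regular by design (six 30 Mb chromosomes, 20 kb loci with
five 400 bp CDS blocks, a fixed blacklist region per chromosome standing in
for HLA/homologous loci, named melanoma genes at fixed slots); intergenic
draws are confined to a guaranteed-noncoding range. Default drivers are a
BRAF V600E-like missense carried by four of six samples and an NRAS
Q61R-like change in one, injected with filter-passing evidence; default CN
events are CDKN2A homozygous deletions in three samples, a KIT one-copy and
PDGFRA two-copy loss in one, and a MITF amplification, carved into a diploid
background tiling.

Every emitted record has exactly one truth row, including a
`should_pass_filter` bit computed directly from the drawn attributes — an
independent restatement of the cascade that the filter must recover exactly.
What the generator does **not** model: read-level data, trinucleotide
context, linkage, sample contamination, or mapping artefacts beyond the
fixed blacklist. Passing tests therefore demonstrate correctness of the
analysis logic under the assumed statistical structure, not robustness to
artefacts real exomes can contain.

## Problem sizes and determinism

The shared test cohort uses 2,000 variants per sample; parameter-recovery
checks use ≥ 5,000 draws (3 SE bands); the end-to-end check runs the full
6 × 5,000 cohort. All randomness flows from a single integer seed through
one `numpy` Generator, and reruns are byte-identical, which the suite
asserts on file checksums; report tables are written with fixed column order
and full row sorts for the same reason.

## Known limitations

- The reference tables are keyed by gene and sample; genomic positions for
  their reconstruction are synthetic stand-ins, so exact-position matching
  is exercised structurally, not against real coordinates.
- Indels and structural variants are out of scope end to end.
- Class-level NS/S counts depend on the curated list's family membership;
  genes absent from the list are invisible to the class screen.
- The concordance analysis assumes array calls are error-free; array
  genotyping error would bias the apparent WES concordance downward.
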