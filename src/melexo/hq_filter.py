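"""High-quality SNV selection cascade and zygosity classification.

The cascade reduces raw per-sample SNV calls to novel, coding, highly
confident variants (HQ-SNVs): it removes known polymorphisms, non-coding
positions, blacklisted regions (HLA loci and homologous repeated genes),
variants seen in prior in-house projects, and calls failing the depth,
quality and allele-fraction thresholds.  Depth is inclusive (>= min_depth);
quality and allele fraction are strict (> min_quality, > min_af), reading the
thresholds literally.  Surviving variants are classified heterozygous or
homozygous from the allele fraction.

Stage order is fixed (known -> coding -> blacklist -> in-house -> depth ->
quality -> AF) for reporting attrition counts, but since every stage is an
independent per-variant predicate the final survivor set does not depend on
the order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from intervaltree import IntervalTree

from .io_formats import (
    CODING_CONSEQUENCES,
    FilterConfig,
    GeneLocus,
    SnvRecord,
)

STAGE_ORDER = ("known", "coding", "blacklist", "in_house", "depth", "quality", "af")


@dataclass(frozen=True)
class HqSnv:
    """An SNV that survived the full cascade, with its zygosity call."""

    record: SnvRecord
    zygosity: str  # heterozygous | homozygous
    filter_trace: tuple[str, ...] = ()

    def __getattr__(self, name):
        # delegate field access to the underlying record
        return getattr(self.record, name)


class GeneIndex:
    """Interval index over CDS intervals for fast coding-overlap queries."""

    def __init__(self, genes: Sequence[GeneLocus]):
        self._trees: dict[str, IntervalTree] = {}
        self.genes = list(genes)
        for g in genes:
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            for s, e in g.cds_intervals:
                # interval tree is half-open; inclusive end -> e + 1
                tree.addi(s, e + 1, g.gene_id)

    def coding_gene(self, chrom: str, pos: int) -> str | None:
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = tree[pos]
        if not hits:
            return None
        # deterministic tie-break when CDS of different genes overlap
        return min(iv.data for iv in hits)


def is_coding(v: SnvRecord, genes: Sequence[GeneLocus] | GeneIndex) -> tuple[bool, str | None]:
    """True iff the position lies within any CDS interval, with the gene id.

    Positions in introns (between CDS intervals of the same gene) or in UTRs
    are non-coding.  When CDS of multiple genes overlap, the
    lexicographically smallest gene id is reported.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    gene = index.coding_gene(v.chrom, v.pos)
    return gene is not None, gene


class RegionIndex:
    """Interval index over closed 1-based regions (blacklist)."""

    def __init__(self, regions: Sequence[tuple[str, int, int]]):
        self._trees: dict[str, IntervalTree] = {}
        for chrom, s, e in regions:
            self._trees.setdefault(chrom, IntervalTree()).addi(s, e + 1, None)

    def __contains__(self, site: tuple[str, int]) -> bool:
        chrom, pos = site
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree[pos])


def in_blacklist(v: SnvRecord,
                 blacklist: Sequence[tuple[str, int, int]] | RegionIndex) -> bool:
    """True iff the variant position falls in a blacklist region (closed ends)."""
    index = blacklist if isinstance(blacklist, RegionIndex) else RegionIndex(blacklist)
    return (v.chrom, v.pos) in index


def classify_zygosity(v: SnvRecord | HqSnv, cfg: FilterConfig = FilterConfig()) -> str:
    """Homozygous iff allele fraction >= hom_af_cutoff, else heterozygous.

    The idealized assignment is AF = 0.5 for heterozygous and AF = 1 for
    homozygous calls; real fractions are noisy, so a single configurable
    cutoff (default 0.85) separates the two.
    """
    af = v.allele_fraction if isinstance(v, SnvRecord) else v.record.allele_fraction
    return "homozygous" if af >= cfg.hom_af_cutoff else "heterozygous"


def apply_hq_filter(
    variants: Sequence[SnvRecord],
    genes: Sequence[GeneLocus] | GeneIndex,
    blacklist: Sequence[tuple[str, int, int]] | RegionIndex,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[HqSnv], dict[str, int]]:
    """Run the full cascade and report per-stage attrition.

    Returns the survivors (with zygosity and the ordered trace of passed
    stages) and a dict mapping each stage to the number of variants it
    removed, plus ``"input"`` and ``"pass"`` totals.  Survivors plus the
    per-stage removals always sum back to the input count.
    """
    gene_index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    bl_index = blacklist if isinstance(blacklist, RegionIndex) else RegionIndex(blacklist)

    counts = {stage: 0 for stage in STAGE_ORDER}
    counts["input"] = len(variants)
    survivors: list[HqSnv] = []
    for v in variants:
        stage = _first_failed_stage(v, gene_index, bl_index, cfg)
        if stage is not None:
            counts[stage] += 1
            continue
        _, gene = is_coding(v, gene_index)
        rec = v if v.gene_id is not None else SnvRecord(
            **{**v.__dict__, "gene_id": gene})
        survivors.append(HqSnv(
            record=rec,
            zygosity=classify_zygosity(v, cfg),
            filter_trace=STAGE_ORDER,
        ))
    counts["pass"] = len(survivors)
    return survivors, counts


def _first_failed_stage(v: SnvRecord, gene_index: GeneIndex,
                        bl_index: RegionIndex, cfg: FilterConfig) -> str | None:
    """The first cascade stage (in STAGE_ORDER) the variant fails, else None."""
    if v.known_flag:
        return "known"
    if v.consequence in CODING_CONSEQUENCES:
        coding = True
    elif v.consequence == "noncoding":
        coding = False
    else:  # unannotated: decide from the gene model
        coding, _ = is_coding(v, gene_index)
    if not coding:
        return "coding"
    if in_blacklist(v, bl_index):
        return "blacklist"
    if v.in_house_flag:
        return "in_house"
    if v.read_depth < cfg.min_depth:
        return "depth"
    if v.call_quality <= cfg.min_quality:
        return "quality"
    if v.allele_fraction <= cfg.min_af:
        return "af"
    return None


def hq_predicate(v: SnvRecord, genes: Sequence[GeneLocus] | GeneIndex,
                 blacklist: Sequence[tuple[str, int, int]] | RegionIndex,
                 cfg: FilterConfig = FilterConfig()) -> bool:
    """Order-free restatement of the cascade as a single boolean predicate."""
    gene_index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    bl_index = blacklist if isinstance(blacklist, RegionIndex) else RegionIndex(blacklist)
    return _first_failed_stage(v, gene_index, bl_index, cfg) is None
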