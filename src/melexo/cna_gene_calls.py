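"""Gene-level copy-number calls from continuous-CN segments.

Segments with CN above ``amp_cn`` (default 2.3) are amplifications and below
``del_cn`` (default 1.3) deletions; a deletion below ``hd_cn`` (default 0.7)
is a two-copy (homozygous) loss.  The published thresholds separate
amplification and deletion only; the one- vs two-copy boundary is not
printed anywhere, so ``hd_cn`` is this package's own configurable constant,
placed symmetrically between CN 1 and CN 0.

A gene is called deleted (or amplified) only when classified segments fully
contain its locus; adjacent same-class deletion segments are merged first,
since segmentation breakpoints are arbitrary.  Partial overlap is reported
as its own status and never as a deletion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import CnSegment, FilterConfig, GeneLocus
from .hq_filter import HqSnv


@dataclass(frozen=True)
class CnaGeneCall:
    sample_id: str
    gene_id: str
    status: str  # amplified | one_copy_loss | homozygous_deletion | neutral | partial_overlap
    cn_value: float | None  # CN of the covering segment (min over merged pieces)


@dataclass(frozen=True)
class CompoundEvent:
    """A non-synonymous mutation on one allele plus loss of the other."""

    sample_id: str
    gene_id: str
    ns_variants: tuple[HqSnv, ...]
    deletion_status: str  # one_copy_loss


def classify_segment(seg: CnSegment, cfg: FilterConfig = FilterConfig()
                     ) -> tuple[str, bool]:
    """(class, hd_flag): amplified / deletion / neutral, hd when CN < hd_cn."""
    if seg.cn_value < 0:
        raise ValueError("negative CN value")
    if seg.cn_value > cfg.amp_cn:
        return "amplified", False
    if seg.cn_value < cfg.del_cn:
        return "deletion", seg.cn_value < cfg.hd_cn
    return "neutral", False


def _merged_runs(segments: Sequence[CnSegment], wanted: str,
                 cfg: FilterConfig) -> list[tuple[int, int, float]]:
    """Maximal runs of adjacent/contiguous same-class segments on one chromosome.

    Returns (start, end, min_cn) spans; a gap between consecutive segments
    breaks the run.
    """
    runs: list[tuple[int, int, float]] = []
    cur: list[CnSegment] = []
    for seg in sorted(segments, key=lambda s: s.start):
        cls, _ = classify_segment(seg, cfg)
        if cls == wanted and (not cur or seg.start == cur[-1].end + 1):
            cur.append(seg)
        else:
            if cur:
                runs.append((cur[0].start, cur[-1].end,
                             min(s.cn_value for s in cur)))
            cur = [seg] if cls == wanted else []
    if cur:
        runs.append((cur[0].start, cur[-1].end, min(s.cn_value for s in cur)))
    return runs


def gene_deletion_status(gene: GeneLocus, segments: Sequence[CnSegment],
                         cfg: FilterConfig = FilterConfig()) -> CnaGeneCall:
    """Gene-level call for one sample from that sample's segments.

    Deleted / amplified only when a merged run of same-class segments
    contains the entire locus; the run's minimum CN decides one-copy loss vs
    homozygous deletion.  Any partial overlap with a non-neutral segment is
    reported as ``partial_overlap``.
    """
    on_chrom = [s for s in segments if s.chrom == gene.chrom]
    sample_id = on_chrom[0].sample_id if on_chrom else ""
    for wanted in ("deletion", "amplified"):
        for start, end, min_cn in _merged_runs(on_chrom, wanted, cfg):
            if start <= gene.start and gene.end <= end:
                if wanted == "amplified":
                    return CnaGeneCall(sample_id, gene.gene_id, "amplified", min_cn)
                status = ("homozygous_deletion" if min_cn < cfg.hd_cn
                          else "one_copy_loss")
                return CnaGeneCall(sample_id, gene.gene_id, status, min_cn)
    # no full containment: does any non-neutral segment touch the gene?
    for seg in on_chrom:
        cls, _ = classify_segment(seg, cfg)
        if cls != "neutral" and seg.start <= gene.end and gene.start <= seg.end:
            return CnaGeneCall(sample_id, gene.gene_id, "partial_overlap",
                               seg.cn_value)
    return CnaGeneCall(sample_id, gene.gene_id, "neutral", None)


def call_genes(genes: Sequence[GeneLocus], segments: Sequence[CnSegment],
               cfg: FilterConfig = FilterConfig()) -> list[CnaGeneCall]:
    """Gene-level calls for every (sample, gene) pair present in ``segments``."""
    by_sample: dict[str, list[CnSegment]] = {}
    for s in segments:
        by_sample.setdefault(s.sample_id, []).append(s)
    calls = []
    for sample_id in sorted(by_sample):
        segs = by_sample[sample_id]
        for gene in genes:
            call = gene_deletion_status(gene, segs, cfg)
            calls.append(CnaGeneCall(sample_id, gene.gene_id, call.status,
                                     call.cn_value))
    return calls


DELETED_STATUSES = ("one_copy_loss", "homozygous_deletion")


def cosmic_deleted_genes(calls: Sequence[CnaGeneCall],
                         cosmic_deleted: Sequence[str] | set[str]
                         ) -> dict[str, object]:
    """Restrict deleted gene calls to a catalogue of known cancer deletions.

    Returns the distinct confirmed genes, per-sample gene lists and counts,
    and the number of samples affected.
    """
    catalogue = set(cosmic_deleted)
    hits = [c for c in calls
            if c.status in DELETED_STATUSES and c.gene_id in catalogue]
    per_sample: dict[str, list[str]] = {}
    for c in hits:
        per_sample.setdefault(c.sample_id, []).append(c.gene_id)
    return {
        "distinct_genes": sorted({c.gene_id for c in hits}),
        "per_sample": {s: sorted(set(g)) for s, g in sorted(per_sample.items())},
        "per_sample_counts": {s: len(set(g)) for s, g in sorted(per_sample.items())},
        "n_samples_affected": len(per_sample),
    }


def compound_events(variants: Sequence[HqSnv],
                    calls: Sequence[CnaGeneCall]) -> list[CompoundEvent]:
    """One event per (sample, gene) with >= 1 NS variant and a one-copy loss.

    The remaining mutated allele plus loss of the other copy is the classical
    two-hit configuration for tumor suppressor inactivation.
    """
    loss = {(c.sample_id, c.gene_id) for c in calls if c.status == "one_copy_loss"}
    ns_by_pair: dict[tuple[str, str], list[HqSnv]] = {}
    for v in variants:
        if v.gene_id and v.consequence in ("missense", "nonsense"):
            ns_by_pair.setdefault((v.sample_id, v.gene_id), []).append(v)
    events = []
    for (sample_id, gene_id) in sorted(loss & set(ns_by_pair)):
        events.append(CompoundEvent(
            sample_id=sample_id, gene_id=gene_id,
            ns_variants=tuple(ns_by_pair[(sample_id, gene_id)]),
            deletion_status="one_copy_loss"))
    return events


def calls_table(calls: Sequence[CnaGeneCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": c.sample_id, "gene_id": c.gene_id, "status": c.status,
        "cn_value": "" if c.cn_value is None else c.cn_value,
    } for c in calls], columns=["sample_id", "gene_id", "status", "cn_value"])
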