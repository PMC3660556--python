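"""Cross-referencing HQ-SNVs against cancer catalogues and curated gene lists.

Catalogue confirmation is an exact-position match (and exact-allele by
default) against COSMIC-style entries.  The curated-list screen groups
mutated genes by the signalling cascade or molecular function they belong
to, counting non-synonymous and synonymous variants per class.  Special
mutation states (truncating, homozygous, double-mutated) are annotated per
variant, and recurrence screens find genes with non-synonymous mutations in
multiple samples — optionally restricted to "de novo" genes absent from both
the cancer catalogue and the curated list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import CatalogueMutation
from .hq_filter import HqSnv


@dataclass(frozen=True)
class MutationAnnotation:
    variant: HqSnv
    matched_catalogue_entry: CatalogueMutation | None = None
    curated_class_tags: frozenset[str] = frozenset()
    is_truncating: bool = False
    is_homozygous: bool = False
    is_double_mutated_gene: bool = False


@dataclass(frozen=True)
class RecurrenceRow:
    gene_id: str
    mutated_samples: frozenset[str]
    n_ns_mutations: int

    def __post_init__(self) -> None:
        if len(self.mutated_samples) < 1:
            raise ValueError("a recurrence row needs at least one sample")
        if self.n_ns_mutations < len(self.mutated_samples):
            raise ValueError("fewer NS mutations than listed samples")


def _is_ns(v: HqSnv) -> bool:
    return v.consequence in ("missense", "nonsense")


def annotate(
    variants: Sequence[HqSnv],
    catalogue: Sequence[CatalogueMutation] | None = None,
    gene_list: Mapping[str, frozenset[str]] | None = None,
    require_allele_match: bool = True,
) -> list[MutationAnnotation]:
    """Full per-variant annotation: catalogue match, curated tags, state flags.

    A variant matches at most one catalogue entry; when several entries share
    a position the first after sorting by (chrom, pos, gene_id, ref, alt)
    wins.  The double-mutated flag marks every non-synonymous variant in a
    (gene, sample) pair carrying two or more distinct non-synonymous variants.
    """
    by_pos: dict[tuple, list[CatalogueMutation]] = {}
    for m in sorted(catalogue or (),
                    key=lambda m: (m.chrom, m.pos, m.gene_id,
                                   m.ref_allele, m.alt_allele)):
        if require_allele_match:
            key = (m.chrom, m.pos, m.ref_allele, m.alt_allele)
        else:
            key = (m.chrom, m.pos)
        by_pos.setdefault(key, []).append(m)

    ns_sites: dict[tuple[str, str], set] = {}
    for v in variants:
        if _is_ns(v) and v.gene_id:
            ns_sites.setdefault((v.gene_id, v.sample_id), set()).add(v.variant_key)

    out = []
    for v in variants:
        if require_allele_match:
            key = (v.chrom, v.pos, v.ref_allele, v.alt_allele)
        else:
            key = (v.chrom, v.pos)
        hits = by_pos.get(key, [])
        double = (v.gene_id is not None and _is_ns(v)
                  and len(ns_sites.get((v.gene_id, v.sample_id), ())) >= 2)
        out.append(MutationAnnotation(
            variant=v,
            matched_catalogue_entry=hits[0] if hits else None,
            curated_class_tags=(gene_list or {}).get(v.gene_id, frozenset())
            if v.gene_id else frozenset(),
            is_truncating=v.consequence == "nonsense",
            is_homozygous=v.zygosity == "homozygous",
            is_double_mutated_gene=double,
        ))
    return out


def match_catalogue(variants: Sequence[HqSnv],
                    catalogue: Sequence[CatalogueMutation],
                    require_allele_match: bool = True) -> list[MutationAnnotation]:
    """Exact-position (and by default exact-allele) catalogue confirmation."""
    return annotate(variants, catalogue=catalogue,
                    require_allele_match=require_allele_match)


def annotate_states(variants: Sequence[HqSnv]) -> list[MutationAnnotation]:
    """Truncating / homozygous / double-mutated state flags only."""
    return annotate(variants)


def confirmed_genes(annotations: Sequence[MutationAnnotation]) -> set[str]:
    """Distinct catalogue genes confirmed by at least one matched variant."""
    return {a.matched_catalogue_entry.gene_id for a in annotations
            if a.matched_catalogue_entry is not None}


def screen_curated(
    variants: Sequence[HqSnv],
    gene_list: Mapping[str, frozenset[str]],
) -> dict[str, dict]:
    """Group curated-list variants by functional class with per-class NS/S.

    A gene listed under k classes contributes its variants to each of the k
    groups; synonymous variants are included in the grouping and counted in
    the per-class S tally.
    """
    classes: dict[str, dict] = {}
    for v in variants:
        if not v.gene_id or v.gene_id not in gene_list:
            continue
        for tag in gene_list[v.gene_id]:
            grp = classes.setdefault(tag, {"variants": [], "n_ns": 0, "n_s": 0,
                                           "genes": set()})
            grp["variants"].append(v)
            grp["genes"].add(v.gene_id)
            if _is_ns(v):
                grp["n_ns"] += 1
            elif v.consequence == "synonymous":
                grp["n_s"] += 1
    return classes


def find_recurrent(variants: Sequence[HqSnv], min_samples: int = 2) -> list[RecurrenceRow]:
    """Genes carrying non-synonymous mutations in >= min_samples samples.

    Rows are sorted by decreasing sample count, then gene id.
    """
    samples: dict[str, set[str]] = {}
    n_ns: dict[str, int] = {}
    for v in variants:
        if not v.gene_id or not _is_ns(v):
            continue
        samples.setdefault(v.gene_id, set()).add(v.sample_id)
        n_ns[v.gene_id] = n_ns.get(v.gene_id, 0) + 1
    rows = [RecurrenceRow(g, frozenset(s), n_ns[g])
            for g, s in samples.items() if len(s) >= min_samples]
    rows.sort(key=lambda r: (-len(r.mutated_samples), r.gene_id))
    return rows


def find_de_novo(
    variants: Sequence[HqSnv],
    cosmic_genes: Iterable[str],
    curated_genes: Iterable[str],
    min_samples: int = 2,
) -> list[RecurrenceRow]:
    """Recurrent genes absent from both the cancer catalogue and curated list."""
    excluded = set(cosmic_genes) | set(curated_genes)
    return [r for r in find_recurrent(variants, min_samples)
            if r.gene_id not in excluded]


def driver_frequency(variants: Sequence, gene_id: str,
                     n_samples: int) -> tuple[float, int]:
    """Carrier fraction of a gene and its floor-rounded percentage.

    ``variants`` is anything with gene_id / sample_id attributes (HQ-SNVs or
    catalogue-confirmation rows).  4 carriers of 6 samples -> (0.666..., 66).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    carriers = {v.sample_id for v in variants if v.gene_id == gene_id}
    frac = len(carriers) / n_samples
    return frac, math.floor(100 * frac)


def samples_with_both(variants: Sequence[HqSnv], gene_a: str,
                      gene_b: str) -> set[str]:
    """Samples carrying NS mutations in both genes (mutual-exclusivity check)."""
    per_gene: dict[str, set[str]] = {gene_a: set(), gene_b: set()}
    for v in variants:
        if v.gene_id in per_gene and _is_ns(v):
            per_gene[v.gene_id].add(v.sample_id)
    return per_gene[gene_a] & per_gene[gene_b]


def recurrence_table(rows: Sequence[RecurrenceRow]):
    import pandas as pd

    return pd.DataFrame([{
        "gene_id": r.gene_id,
        "n_mutated_samples": len(r.mutated_samples),
        "mutated_samples": ",".join(sorted(r.mutated_samples)),
        "n_ns_mutations": r.n_ns_mutations,
    } for r in rows], columns=["gene_id", "n_mutated_samples",
                               "mutated_samples", "n_ns_mutations"])
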