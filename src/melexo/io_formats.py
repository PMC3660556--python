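"""Readers, writers and domain types for every format the pipeline touches.

All genomic coordinates are held 1-based inclusive internally (the VCF
convention, since variants are the central object); BED inputs are converted
at the boundary and converted back on write.

Tabular inputs (gene models, copy-number segments, array genotypes,
catalogues, curated gene lists) are plain TSV with documented column schemas;
unknown columns are ignored with a warning so that richer exports from other
tools can be consumed directly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
import yaml

logger = logging.getLogger("melexo")

BASES = frozenset("ACGT")

CONSEQUENCES = ("synonymous", "missense", "nonsense", "noncoding", "unannotated")
CODING_CONSEQUENCES = ("synonymous", "missense", "nonsense")

GENOTYPES = ("hom_ref", "het", "hom_alt")


class FormatError(ValueError):
    """A file failed to parse or validate against its schema."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnvRecord:
    """One called single-nucleotide variant flowing through the filter cascade.

    ``allele_fraction`` is the fraction of non-reference reads among all reads
    covering the site, in [0, 1]; for a clean heterozygous call it sits near
    0.5 and for a homozygous non-reference call near 1.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    read_depth: int
    call_quality: float
    allele_fraction: float
    known_flag: bool = False
    in_house_flag: bool = False
    gene_id: str | None = None
    consequence: str = "unannotated"

    def __post_init__(self) -> None:
        if self.ref_allele not in BASES or self.alt_allele not in BASES:
            raise FormatError(
                f"alleles must be single bases, got {self.ref_allele!r}>{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise FormatError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise FormatError(f"pos must be >= 1, got {self.pos}")
        if self.read_depth < 0:
            raise FormatError(f"read_depth must be >= 0, got {self.read_depth}")
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise FormatError(f"allele_fraction outside [0,1]: {self.allele_fraction}")
        if self.consequence not in CONSEQUENCES:
            raise FormatError(f"unknown consequence {self.consequence!r}")

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def variant_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class GeneLocus:
    """Gene span with CDS intervals and functional-class tags.

    ``cds_intervals`` are 1-based inclusive, non-overlapping and contained in
    ``[start, end]``; ``class_tags`` carry curated functional groupings such as
    "MAPK signalling".
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    cds_intervals: tuple[tuple[int, int], ...] = ()
    class_tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: strand must be + or -")
        prev_end = None
        for s, e in sorted(self.cds_intervals):
            if s > e:
                raise FormatError(f"{self.gene_id}: CDS interval {s}-{e} inverted")
            if s < self.start or e > self.end:
                raise FormatError(
                    f"{self.gene_id}: CDS interval {s}-{e} outside gene span "
                    f"{self.start}-{self.end}"
                )
            if prev_end is not None and s <= prev_end:
                raise FormatError(f"{self.gene_id}: CDS intervals overlap")
            prev_end = e
        object.__setattr__(self, "cds_intervals", tuple(sorted(self.cds_intervals)))
        object.__setattr__(self, "class_tags", frozenset(self.class_tags))


@dataclass(frozen=True)
class CnSegment:
    """Per-sample copy-number segment with a continuous CN estimate."""

    sample_id: str
    chrom: str
    start: int
    end: int
    cn_value: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"segment start {self.start} > end {self.end}")
        if self.cn_value < 0:
            raise FormatError(f"cn_value must be >= 0, got {self.cn_value}")


@dataclass(frozen=True)
class ArrayGenotype:
    """Orthogonal genotype call at a SNP site (array treated as gold standard)."""

    sample_id: str
    chrom: str
    pos: int
    genotype: str  # hom_ref | het | hom_alt
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise FormatError(f"unknown genotype code {self.genotype!r}")
        if self.ref_allele == self.alt_allele:
            raise FormatError("array site alleles must differ")


@dataclass(frozen=True)
class CatalogueMutation:
    """Known cancer mutation keyed by exact genomic position and alleles."""

    gene_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise FormatError("catalogue alleles must differ")
        if self.pos < 1:
            raise FormatError(f"pos must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class FilterConfig:
    """Every numeric threshold used across the pipeline, in one place.

    Defaults reproduce the published filtering regime: variants need at least
    ``min_depth`` reads (inclusive), a call quality strictly above
    ``min_quality`` and a non-reference allele fraction strictly above
    ``min_af``.  Copy-number segments above ``amp_cn`` are amplifications and
    below ``del_cn`` deletions; below ``hd_cn`` a deletion is treated as a
    two-copy (homozygous) loss.  ``hom_af_cutoff`` separates heterozygous from
    homozygous variant calls, and ``plateau_level`` is the sustained
    heterozygous-concordance level that fixes the minimum calling depth.
    """

    min_depth: int = 15
    min_quality: float = 150.0
    min_af: float = 0.20
    amp_cn: float = 2.3
    del_cn: float = 1.3
    hd_cn: float = 0.7
    hom_af_cutoff: float = 0.85
    plateau_level: float = 0.90
    recurrence_min_samples: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.min_af < self.hom_af_cutoff <= 1):
            raise FormatError(
                f"need 0 < min_af < hom_af_cutoff <= 1, got {self.min_af}, {self.hom_af_cutoff}"
            )
        if not (self.hd_cn < self.del_cn < self.amp_cn):
            raise FormatError(
                f"need hd_cn < del_cn < amp_cn, got {self.hd_cn}, {self.del_cn}, {self.amp_cn}"
            )
        if not (0 < self.plateau_level <= 1):
            raise FormatError(f"plateau_level outside (0,1]: {self.plateau_level}")
        if self.min_depth < 0 or self.min_quality < 0:
            raise FormatError("depth/quality thresholds must be non-negative")
        if self.recurrence_min_samples < 1:
            raise FormatError("recurrence_min_samples must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            logger.warning("ignoring unknown config keys: %s", sorted(unknown))
        return cls(**{k: v for k, v in data.items() if k in known})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Coordinate conversion
# ---------------------------------------------------------------------------

def bed_to_internal(start0: int, end0: int) -> tuple[int, int]:
    """Convert a BED half-open interval [start0, end0) to 1-based inclusive."""
    return start0 + 1, end0


def internal_to_bed(start1: int, end1: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval back to BED half-open."""
    return start1 - 1, end1


# ---------------------------------------------------------------------------
# VCF variants
# ---------------------------------------------------------------------------

def read_variants(
    path: str | Path,
    sample_id: str,
    known_sites: Iterable[tuple[str, int, str, str]] | None = None,
    in_house: Iterable[tuple[str, int, str, str]] | None = None,
) -> list[SnvRecord]:
    """Read biallelic SNVs for one sample from a VCF.

    Multi-allelic lines are split into one record per alternate allele;
    non-SNV alleles (indels, symbolic) are skipped and the skip count logged.
    Depth comes from FORMAT/DP (falling back to INFO/DP), call quality from
    the QUAL column, and the allele fraction is recomputed as
    alt_reads / (ref_reads + alt_reads) from FORMAT/AD when present, else
    taken from FORMAT/AF or INFO/AF.  ``known_sites`` and ``in_house``
    are membership sets of (chrom, pos, ref, alt) keys used to set the
    corresponding flags.
    """
    known = set(known_sites) if known_sites is not None else set()
    house = set(in_house) if in_house is not None else set()
    records: list[SnvRecord] = []
    n_skipped = 0
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"malformed VCF {path}: {exc}") from exc
    with vcf:
        for rec in vcf:
            ref = rec.ref
            for alt_idx, alt in enumerate(rec.alts or ()):
                if ref is None or len(ref) != 1 or alt is None or len(alt) != 1 \
                        or ref not in BASES or alt not in BASES:
                    n_skipped += 1
                    continue
                depth, af = _depth_and_af(rec, alt_idx)
                if depth is None:
                    raise FormatError(
                        f"{path}: no depth field (FORMAT/DP, AD or INFO/DP) at "
                        f"{rec.chrom}:{rec.pos}"
                    )
                if af is None:
                    raise FormatError(
                        f"{path}: no allele-fraction source (FORMAT/AD, AF or "
                        f"INFO/AF) at {rec.chrom}:{rec.pos}"
                    )
                gene = _info_get(rec, "GENE")
                conseq = _info_get(rec, "CONSEQ") or "unannotated"
                if isinstance(gene, tuple):
                    gene = gene[0]
                if isinstance(conseq, tuple):
                    conseq = conseq[0]
                key = (rec.chrom, rec.pos, ref, alt)
                records.append(SnvRecord(
                    sample_id=sample_id,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    read_depth=int(depth),
                    call_quality=float(rec.qual if rec.qual is not None else 0.0),
                    allele_fraction=float(af),
                    known_flag=key in known,
                    in_house_flag=key in house,
                    gene_id=gene,
                    consequence=str(conseq),
                ))
    if n_skipped:
        logger.info("%s: skipped %d non-SNV allele(s)", path, n_skipped)
    return records


def _info_get(rec, key: str):
    """INFO lookup tolerant of keys absent from the header."""
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _depth_and_af(rec, alt_idx: int):
    """Extract (depth, allele_fraction) for one alt allele of a VCF record."""
    depth = None
    af = None
    if rec.samples:
        fmt = rec.samples[0]
        ad = fmt.get("AD")
        if ad is not None and ad[0] is not None:
            ref_reads = int(ad[0])
            alt_reads = int(ad[alt_idx + 1]) if len(ad) > alt_idx + 1 else 0
            total = ref_reads + sum(int(a) for a in ad[1:] if a is not None)
            depth = total
            af = alt_reads / total if total > 0 else 0.0
        dp = fmt.get("DP")
        if dp is not None:
            depth = int(dp)
        if af is None:
            faf = fmt.get("AF")
            if faf is not None:
                af = faf[alt_idx] if isinstance(faf, tuple) else faf
    if depth is None and "DP" in rec.info:
        depth = int(rec.info["DP"])
    if af is None and "AF" in rec.info:
        iaf = rec.info["AF"]
        af = iaf[alt_idx] if isinstance(iaf, tuple) else iaf
    return depth, af


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene identifier">
##INFO=<ID=CONSEQ,Number=1,Type=String,Description="Functional consequence">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""


def write_variants(records: Sequence[SnvRecord], path: str | Path, sample_id: str) -> None:
    """Write one sample's SNVs as a minimal single-sample VCF 4.2.

    Allelic depths are encoded so that alt_reads / depth reproduces the
    record's allele fraction exactly on re-read (the fraction is therefore
    quantized to the depth grid; records built from read counts round-trip
    bit-exactly).
    """
    recs = sorted(records, key=lambda r: (r.chrom, r.pos, r.alt_allele))
    chroms = sorted({r.chrom for r in recs})
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_id}\n")
        for r in recs:
            alt_reads = round(r.allele_fraction * r.read_depth)
            ref_reads = r.read_depth - alt_reads
            info = []
            if r.gene_id:
                info.append(f"GENE={r.gene_id}")
            info.append(f"CONSEQ={r.consequence}")
            gt = "1/1" if r.allele_fraction >= 0.85 else "0/1"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref_allele}\t{r.alt_allele}\t"
                f"{r.call_quality:g}\t.\t{';'.join(info)}\t"
                f"GT:DP:AD\t{gt}:{r.read_depth}:{ref_reads},{alt_reads}\n"
            )


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:
        raise FormatError(f"cannot parse TSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, extra)
    return df


# ---------------------------------------------------------------------------
# Gene model
# ---------------------------------------------------------------------------

def read_gene_model(path: str | Path) -> list[GeneLocus]:
    """Read a gene model from TSV (or BED12) into validated loci.

    TSV columns: gene_id, chrom, start, end (1-based inclusive), strand,
    cds_intervals ("s-e,s-e", 1-based inclusive), class_tags (";"-separated,
    may be empty).  A ``.bed`` path is parsed as BED12 with block coordinates
    converted from half-open to 1-based inclusive.
    """
    path = Path(path)
    loci = _read_gene_model_bed(path) if path.suffix == ".bed" else _read_gene_model_tsv(path)
    seen: set[str] = set()
    for g in loci:
        if g.gene_id in seen:
            raise FormatError(f"{path}: duplicate gene_id {g.gene_id}")
        seen.add(g.gene_id)
    return loci


def _read_gene_model_tsv(path: Path) -> list[GeneLocus]:
    df = _read_tsv(path, ["gene_id", "chrom", "start", "end", "strand",
                          "cds_intervals", "class_tags"])
    loci = []
    for row in df.itertuples(index=False):
        cds = []
        if isinstance(row.cds_intervals, str) and row.cds_intervals:
            for part in row.cds_intervals.split(","):
                s, e = part.split("-")
                cds.append((int(s), int(e)))
        tags = frozenset(t for t in str(row.class_tags or "").split(";")
                         if t and t != "nan")
        loci.append(GeneLocus(
            gene_id=row.gene_id, chrom=row.chrom,
            start=int(row.start), end=int(row.end), strand=row.strand,
            cds_intervals=tuple(cds), class_tags=tags,
        ))
    return loci


def _read_gene_model_bed(path: Path) -> list[GeneLocus]:
    loci = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{i}: BED gene rows need >= 6 columns")
            start1, end1 = bed_to_internal(int(f[1]), int(f[2]))
            cds: list[tuple[int, int]] = []
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                for size, off in zip(sizes, offsets):
                    bs, be = bed_to_internal(int(f[1]) + off, int(f[1]) + off + size)
                    cds.append((bs, be))
            loci.append(GeneLocus(gene_id=f[3], chrom=f[0], start=start1,
                                  end=end1, strand=f[5],
                                  cds_intervals=tuple(cds)))
    return loci


def write_gene_model(loci: Sequence[GeneLocus], path: str | Path) -> None:
    rows = [{
        "gene_id": g.gene_id, "chrom": g.chrom, "start": g.start, "end": g.end,
        "strand": g.strand,
        "cds_intervals": ",".join(f"{s}-{e}" for s, e in g.cds_intervals),
        "class_tags": ";".join(sorted(g.class_tags)),
    } for g in sorted(loci, key=lambda g: (g.chrom, g.start, g.gene_id))]
    pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand",
                                "cds_intervals", "class_tags"]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Blacklist BED
# ---------------------------------------------------------------------------

def read_blacklist(path: str | Path) -> list[tuple[str, int, int]]:
    """Read blacklist regions (BED half-open) as 1-based inclusive intervals."""
    regions = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{i}: BED rows need >= 3 columns")
            s, e = bed_to_internal(int(f[1]), int(f[2]))
            regions.append((f[0], s, e))
    return regions


def write_blacklist(regions: Sequence[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in sorted(regions):
            s0, e0 = internal_to_bed(s, e)
            fh.write(f"{chrom}\t{s0}\t{e0}\n")


# ---------------------------------------------------------------------------
# Segments, array genotypes, catalogues, gene lists
# ---------------------------------------------------------------------------

def read_segments(path: str | Path) -> list[CnSegment]:
    """Read SEG-like TSV (sample_id, chrom, start, end, cn_value).

    Same-sample segments on one chromosome must not overlap.
    """
    df = _read_tsv(path, ["sample_id", "chrom", "start", "end", "cn_value"])
    segs = [CnSegment(row.sample_id, row.chrom, int(row.start), int(row.end),
                      float(row.cn_value))
            for row in df.itertuples(index=False)]
    validate_segments(segs)
    return segs


def validate_segments(segs: Sequence[CnSegment]) -> None:
    by_key: dict[tuple[str, str], list[CnSegment]] = {}
    for s in segs:
        by_key.setdefault((s.sample_id, s.chrom), []).append(s)
    for (sample, chrom), group in by_key.items():
        group.sort(key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if b.start <= a.end:
                raise FormatError(
                    f"overlapping segments for {sample} on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


def write_segments(segs: Sequence[CnSegment], path: str | Path) -> None:
    rows = [{"sample_id": s.sample_id, "chrom": s.chrom, "start": s.start,
             "end": s.end, "cn_value": s.cn_value}
            for s in sorted(segs, key=lambda s: (s.sample_id, s.chrom, s.start))]
    pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "cn_value"]
                 ).to_csv(path, sep="\t", index=False)


def read_array_genotypes(path: str | Path) -> list[ArrayGenotype]:
    """Read array genotype TSV (sample_id, chrom, pos, genotype, ref, alt)."""
    df = _read_tsv(path, ["sample_id", "chrom", "pos", "genotype",
                          "ref_allele", "alt_allele"])
    return [ArrayGenotype(row.sample_id, row.chrom, int(row.pos), row.genotype,
                          row.ref_allele, row.alt_allele)
            for row in df.itertuples(index=False)]


def write_array_genotypes(calls: Sequence[ArrayGenotype], path: str | Path) -> None:
    rows = [{"sample_id": a.sample_id, "chrom": a.chrom, "pos": a.pos,
             "genotype": a.genotype, "ref_allele": a.ref_allele,
             "alt_allele": a.alt_allele}
            for a in sorted(calls, key=lambda a: (a.sample_id, a.chrom, a.pos))]
    pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "genotype",
                                "ref_allele", "alt_allele"]
                 ).to_csv(path, sep="\t", index=False)


def read_catalogue(path: str | Path) -> list[CatalogueMutation]:
    """Read a known-mutation catalogue TSV (gene_id, chrom, pos, ref, alt, source)."""
    df = _read_tsv(path, ["gene_id", "chrom", "pos", "ref_allele",
                          "alt_allele", "source_label"])
    return [CatalogueMutation(row.gene_id, row.chrom, int(row.pos),
                              row.ref_allele, row.alt_allele,
                              "" if pd.isna(row.source_label) else str(row.source_label))
            for row in df.itertuples(index=False)]


def write_catalogue(entries: Sequence[CatalogueMutation], path: str | Path) -> None:
    rows = [{"gene_id": m.gene_id, "chrom": m.chrom, "pos": m.pos,
             "ref_allele": m.ref_allele, "alt_allele": m.alt_allele,
             "source_label": m.source_label}
            for m in sorted(entries, key=lambda m: (m.chrom, m.pos, m.gene_id))]
    pd.DataFrame(rows, columns=["gene_id", "chrom", "pos", "ref_allele",
                                "alt_allele", "source_label"]
                 ).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a curated gene list TSV (gene_id, class_tags) -> gene -> tag set.

    A gene may belong to several functional classes; tags are ";"-separated.
    """
    df = _read_tsv(path, ["gene_id", "class_tags"])
    out: dict[str, frozenset[str]] = {}
    for row in df.itertuples(index=False):
        tags = frozenset(t for t in str(row.class_tags or "").split(";")
                         if t and t != "nan")
        if row.gene_id in out:
            out[row.gene_id] = out[row.gene_id] | tags
        else:
            out[row.gene_id] = tags
    return out


def write_gene_list(genes: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [{"gene_id": g, "class_tags": ";".join(sorted(tags))}
            for g, tags in sorted(genes.items())]
    pd.DataFrame(rows, columns=["gene_id", "class_tags"]).to_csv(
        path, sep="\t", index=False)


def read_site_set(path: str | Path) -> set[tuple[str, int, str, str]]:
    """Read a variant-site membership set (chrom, pos, ref_allele, alt_allele).

    Used for the known-polymorphism catalogue and the in-house prior-projects
    set consumed by the filter cascade.
    """
    df = _read_tsv(path, ["chrom", "pos", "ref_allele", "alt_allele"])
    return {(r.chrom, int(r.pos), r.ref_allele, r.alt_allele)
            for r in df.itertuples(index=False)}


def write_site_set(sites: Iterable[tuple[str, int, str, str]],
                   path: str | Path) -> None:
    rows = [{"chrom": c, "pos": p, "ref_allele": r, "alt_allele": a}
            for c, p, r, a in sorted(sites)]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref_allele", "alt_allele"]
                 ).to_csv(path, sep="\t", index=False)


def read_depth_sites(path: str | Path) -> pd.DataFrame:
    """Read homozygous-reference evidence sites (sample_id, chrom, pos, read_depth)."""
    df = _read_tsv(path, ["sample_id", "chrom", "pos", "read_depth"])
    return df.astype({"pos": int, "read_depth": int})


def write_depth_sites(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["sample_id", "chrom", "pos", "read_depth"]
    df[cols].sort_values(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                 scalars: Mapping[str, object] | None = None) -> dict[str, str]:
    """Write result tables as TSV plus a JSON index with checksums.

    Rows are sorted on all columns and columns emitted in a fixed order, so
    re-running on the same inputs yields byte-identical files.  Returns the
    per-file sha256 map that is also written to ``report.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}
    for name, df in sorted(tables.items()):
        p = out_dir / f"{name}.tsv"
        out = df.sort_values(list(df.columns)) if len(df) else df
        out.to_csv(p, sep="\t", index=False)
        checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    index = {
        "tables": {n: {"rows": int(len(tables[n])), "sha256": checksums[f"{n}.tsv"]}
                   for n in sorted(tables)},
        "scalars": dict(scalars or {}),
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(index, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return checksums
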