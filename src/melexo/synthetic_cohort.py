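"""Synthetic multi-sample exome cohort with full ground truth.

The generator emulates the statistical structure the downstream analysis
assumes for a small panel of metastatic melanoma cell lines: six samples, a
UV-dominated substitution spectrum (C>T/G>A transitions carrying most of the
weight), a majority of known polymorphisms over novel variants, negative-
binomial read depths around a 45x mean, allele fractions derived from
binomial sampling of reads at heterozygous sites, injected driver mutations
(a BRAF V600E-like change carried by four of six samples, an NRAS Q61R-like
change in one), and copy-number segments containing amplifications, one-copy
losses and homozygous deletions on a diploid background.

Everything emitted is accompanied by a truth table so downstream stages can
be scored exactly.  What the generator deliberately does *not* model:
read-level data, trinucleotide sequence context, linkage between sites, and
mapping artefacts beyond a fixed positional blacklist.

All randomness flows from a single seed; the same spec and seed reproduce
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io_formats as io
from .io_formats import (
    ArrayGenotype,
    CatalogueMutation,
    CnSegment,
    GeneLocus,
    SnvRecord,
)
from .spectrum_stats import CLASSES

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# class label -> (pyrimidine-strand ref/alt, purine-strand ref/alt)
_CLASS_PAIRS = {
    label: ((label[0], label[2]), (_COMPLEMENT[label[0]], _COMPLEMENT[label[2]]))
    for label in CLASSES
}

DEFAULT_SAMPLES = ("Me01", "Me02", "Me04", "Me05", "Me08", "Me12")

#: Default collapsed-class weights: C>T/G>A dominance as under UV exposure.
DEFAULT_SPECTRUM = (0.60, 0.10, 0.08, 0.12, 0.05, 0.05)

CHROM_LENGTH = 30_000_000
GENE_REGION_END = 10_000_000       # genes live in the first 10 Mb
NONCODING_START = 15_000_000       # guaranteed-intergenic draw range
NONCODING_END = 29_000_000


@dataclass(frozen=True)
class DriverSpec:
    """An injected driver mutation and the samples that carry it."""

    gene_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    carriers: tuple[str, ...]
    zygosity: str = "heterozygous"
    consequence: str = "missense"


@dataclass(frozen=True)
class CnEventSpec:
    sample_id: str
    chrom: str
    start: int
    end: int
    cn_value: float


@dataclass
class CohortSpec:
    """Every knob of the generator, with defaults set to the study conditions."""

    n_samples: int = 6
    seed: int = 0
    n_variants_per_sample: int = 5000
    spectrum_weights: tuple[float, ...] = DEFAULT_SPECTRUM
    novel_fraction: float = 0.08
    coding_fraction: float = 0.20
    het_fraction: float = 0.80
    in_house_fraction: float = 0.02
    consequence_weights: tuple[float, float, float] = (0.34, 0.62, 0.04)  # S, mis, non
    depth_mean: float = 45.0
    depth_dispersion: float = 8.0          # negative-binomial shape (larger = tighter)
    quality_shape: float = 4.0
    quality_scale: float = 60.0            # gamma; mean 240, ~24% below 150
    af_noise_sd: float = 0.02
    het_allele_sampling: bool = True
    array_sites: int = 1000
    array_variant_fraction: float = 0.5    # share of array sites placed on variants
    drivers: tuple[DriverSpec, ...] | None = None   # None -> defaults
    cn_events: tuple[CnEventSpec, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if abs(sum(self.spectrum_weights) - 1.0) > 1e-9:
            raise ValueError("spectrum_weights must sum to 1")
        if len(self.spectrum_weights) != 6 or any(w < 0 for w in self.spectrum_weights):
            raise ValueError("spectrum_weights must be 6 non-negative reals")
        for name in ("novel_fraction", "coding_fraction", "het_fraction",
                     "in_house_fraction", "array_variant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0,1]: {v}")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        if self.n_samples <= len(DEFAULT_SAMPLES):
            return DEFAULT_SAMPLES[: self.n_samples]
        return DEFAULT_SAMPLES + tuple(
            f"Me{i:02d}" for i in range(13, 13 + self.n_samples - len(DEFAULT_SAMPLES)))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Gene model and static context
# ---------------------------------------------------------------------------

#: (gene name, chromosome index, class tags) for the named genes of the model.
_NAMED_GENES = (
    ("NRAS", 0, ("RAS-RAF Ser/Thr kinases", "MAPK signalling")),
    ("MITF", 2, ("Transcription factors",)),
    ("KIT", 3, ("Protein tyrosine kinases",)),
    ("PDGFRA", 3, ("Protein tyrosine kinases",)),
    ("BRAF", 5, ("RAS-RAF Ser/Thr kinases", "MAPK signalling")),
    ("CDKN2A", 4, ("Cell cycle regulators",)),
    ("PTEN", 1, ("PI3K/Akt signalling",)),
    ("GRM1", 2, ("Glutamate signalling", "G protein-coupled receptors")),
)


def make_gene_model(n_genes_per_chrom: int = 60, n_chroms: int = 6) -> list[GeneLocus]:
    """Regularly spaced synthetic gene model with CDS blocks and class tags.

    Genes occupy the first 10 Mb of each chromosome: 20 kb loci every 150 kb,
    each with five 400 bp CDS intervals.  Gene slot 1 of every chromosome
    falls inside the fixed blacklist region (an HLA-like / homologous-repeat
    stand-in), and a handful of named melanoma genes replace the generic ids
    at fixed slots so drivers and catalogues have stable anchors.
    """
    # place each named gene on its own slot on the requested chromosome
    slots: dict[tuple[int, int], tuple[str, tuple[str, ...]]] = {}
    per_chrom_next: dict[int, int] = {}
    for name, chrom_idx, tags in _NAMED_GENES:
        slot = per_chrom_next.get(chrom_idx, 2)
        slots[(chrom_idx, slot)] = (name, tags)
        per_chrom_next[chrom_idx] = slot + 1

    genes: list[GeneLocus] = []
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        for gi in range(n_genes_per_chrom):
            start = 100_000 + gi * 150_000
            end = start + 19_999
            cds = tuple((start + k * 4000, start + k * 4000 + 399) for k in range(5))
            name, tags = slots.get((ci, gi), (f"GENE_{chrom}_{gi:03d}", ()))
            genes.append(GeneLocus(
                gene_id=name, chrom=chrom, start=start, end=end, strand="+",
                cds_intervals=cds, class_tags=frozenset(tags)))
    return genes


def make_blacklist(n_chroms: int = 6) -> list[tuple[str, int, int]]:
    """One fixed region per chromosome covering gene slot 1 (1-based inclusive)."""
    regions = []
    for ci in range(n_chroms):
        start = 100_000 + 1 * 150_000
        regions.append((f"chr{ci + 1}", start, start + 19_999))
    return regions


def _cds_position(gene: GeneLocus, offset: int) -> int:
    """The ``offset``-th coding base of a gene (0-based across CDS intervals)."""
    for s, e in gene.cds_intervals:
        span = e - s + 1
        if offset < span:
            return s + offset
        offset -= span
    raise ValueError(f"offset beyond CDS of {gene.gene_id}")


def default_drivers(genes: Sequence[GeneLocus],
                    sample_ids: Sequence[str]) -> tuple[DriverSpec, ...]:
    """BRAF V600E-like in four samples, NRAS Q61R-like in one other sample."""
    by_id = {g.gene_id: g for g in genes}
    drivers = []
    if "BRAF" in by_id and len(sample_ids) >= 1:
        carriers = tuple(s for s in sample_ids if s in
                         ("Me01", "Me04", "Me08", "Me12")) or (sample_ids[0],)
        drivers.append(DriverSpec(
            gene_id="BRAF", pos=_cds_position(by_id["BRAF"], 1798),
            ref_allele="T", alt_allele="A", carriers=carriers))
    if "NRAS" in by_id and len(sample_ids) >= 2:
        carriers = ("Me02",) if "Me02" in sample_ids else (sample_ids[1],)
        drivers.append(DriverSpec(
            gene_id="NRAS", pos=_cds_position(by_id["NRAS"], 181),
            ref_allele="A", alt_allele="G", carriers=carriers))
    return tuple(drivers)


def default_cn_events(genes: Sequence[GeneLocus],
                      sample_ids: Sequence[str]) -> tuple[CnEventSpec, ...]:
    """Homozygous CDKN2A losses, a one-copy KIT loss and a MITF amplification."""
    by_id = {g.gene_id: g for g in genes}
    events = []

    def spanning(gene_id: str, sample: str, cn: float, pad: int = 50_000):
        g = by_id[gene_id]
        return CnEventSpec(sample, g.chrom, max(1, g.start - pad), g.end + pad, cn)

    present = [s for s in ("Me01", "Me02", "Me12") if s in sample_ids]
    for s in present:
        if "CDKN2A" in by_id:
            events.append(spanning("CDKN2A", s, 0.0))
    if "KIT" in by_id and "Me05" in sample_ids:
        events.append(spanning("KIT", "Me05", 1.0))
        if "PDGFRA" in by_id:
            events.append(spanning("PDGFRA", "Me05", 0.4))
    if "MITF" in by_id and "Me08" in sample_ids:
        events.append(spanning("MITF", "Me08", 3.8))
    return tuple(events)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """In-memory view of an emitted cohort plus its output directory."""

    spec: CohortSpec
    out_dir: Path
    genes: list[GeneLocus]
    blacklist: list[tuple[str, int, int]]
    variants: dict[str, list[SnvRecord]]          # sample -> records
    array_genotypes: list[ArrayGenotype]
    homref_sites: pd.DataFrame
    segments: list[CnSegment]
    known_sites: set[tuple[str, int, str, str]]
    in_house_sites: set[tuple[str, int, str, str]]
    cosmic_mutations: list[CatalogueMutation]
    cosmic_deleted: list[str]
    curated_genes: dict[str, frozenset[str]]
    truth_variants: pd.DataFrame
    truth_cn: pd.DataFrame

    def vcf_path(self, sample_id: str) -> Path:
        return self.out_dir / f"{sample_id}.vcf"


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> CohortBundle:
    """Generate and write the full cohort; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genes = make_gene_model()
    blacklist = make_blacklist()
    sample_ids = spec.sample_ids
    drivers = spec.drivers if spec.drivers is not None else \
        default_drivers(genes, sample_ids)
    cn_events = spec.cn_events if spec.cn_events is not None else \
        default_cn_events(genes, sample_ids)
    _validate_drivers(drivers, genes)

    coding_pool, pool_genes = _coding_pool(genes)

    rows: list[dict] = []
    for sample_id in sample_ids:
        rows.extend(_sample_variants(spec, rng, sample_id, genes,
                                     coding_pool, pool_genes))

    truth = pd.DataFrame(rows)
    truth = _assign_site_flags(truth, drivers, spec, rng)
    truth = _inject_drivers(truth, drivers, spec)
    truth["blacklisted"] = _in_regions(truth, blacklist)
    truth["coding"] = truth["consequence"].isin(io.CODING_CONSEQUENCES)
    truth["should_pass_filter"] = (
        ~truth["known"] & truth["coding"] & ~truth["blacklisted"]
        & ~truth["in_house"]
        & (truth["read_depth"] >= 15) & (truth["call_quality"] > 150)
        & (truth["allele_fraction"] > 0.20)
    )
    truth = truth.sort_values(["sample_id", "chrom", "pos"]).reset_index(drop=True)

    variants = _records_from_truth(truth)
    array_calls, homref = generate_array_genotypes(spec, truth, rng)
    segments = generate_cn_segments(spec, cn_events, genes)
    truth_cn = _cn_truth(cn_events, genes, sample_ids)

    known = {tuple(t) for t in
             truth.loc[truth["known"], ["chrom", "pos", "ref_allele",
                                        "alt_allele"]].itertuples(index=False)}
    house = {tuple(t) for t in
             truth.loc[truth["in_house"], ["chrom", "pos", "ref_allele",
                                           "alt_allele"]].itertuples(index=False)}
    cosmic = [CatalogueMutation(d.gene_id, _gene_by_id(genes, d.gene_id).chrom,
                                d.pos, d.ref_allele, d.alt_allele,
                                "malignant melanoma")
              for d in drivers]
    cosmic_deleted = sorted({_gene_for_event(e, genes) for e in cn_events
                             if e.cn_value < 1.3} - {None})
    curated = {g.gene_id: g.class_tags for g in genes if g.class_tags}

    bundle = CohortBundle(
        spec=spec, out_dir=out_dir, genes=genes, blacklist=blacklist,
        variants=variants, array_genotypes=array_calls, homref_sites=homref,
        segments=segments, known_sites=known, in_house_sites=house,
        cosmic_mutations=cosmic, cosmic_deleted=cosmic_deleted,
        curated_genes=curated, truth_variants=truth, truth_cn=truth_cn)
    _write_bundle(bundle)
    return bundle


def _validate_drivers(drivers: Sequence[DriverSpec],
                      genes: Sequence[GeneLocus]) -> None:
    by_id = {g.gene_id: g for g in genes}
    for d in drivers:
        g = by_id.get(d.gene_id)
        if g is None:
            raise ValueError(f"driver gene {d.gene_id} not in gene model")
        if not any(s <= d.pos <= e for s, e in g.cds_intervals):
            raise ValueError(
                f"driver position {d.pos} outside CDS of {d.gene_id}")


def _gene_by_id(genes: Sequence[GeneLocus], gene_id: str) -> GeneLocus:
    return next(g for g in genes if g.gene_id == gene_id)


def _gene_for_event(event: CnEventSpec, genes: Sequence[GeneLocus]) -> str | None:
    """The gene a CN event fully contains (the event's intended target)."""
    for g in genes:
        if g.chrom == event.chrom and event.start <= g.start and g.end <= event.end:
            return g.gene_id
    return None


def _coding_pool(genes: Sequence[GeneLocus]) -> tuple[np.ndarray, list[GeneLocus]]:
    """Cumulative CDS lengths for length-weighted coding position draws."""
    lengths = np.array([sum(e - s + 1 for s, e in g.cds_intervals)
                        for g in genes])
    return np.cumsum(lengths), list(genes)


def _sample_variants(spec: CohortSpec, rng: np.random.Generator,
                     sample_id: str, genes: Sequence[GeneLocus],
                     coding_cum: np.ndarray,
                     pool_genes: Sequence[GeneLocus]) -> list[dict]:
    n = spec.n_variants_per_sample
    n_coding = rng.binomial(n, spec.coding_fraction)

    chroms: list[str] = []
    positions: list[int] = []
    gene_ids: list[str | None] = []
    total_cds = int(coding_cum[-1])
    offsets = rng.integers(0, total_cds, size=n_coding)
    for off in offsets:
        gi = int(np.searchsorted(coding_cum, off, side="right"))
        g = pool_genes[gi]
        local = int(off - (coding_cum[gi - 1] if gi else 0))
        chroms.append(g.chrom)
        positions.append(_cds_position(g, local))
        gene_ids.append(g.gene_id)
    n_nc = n - n_coding
    nc_chrom = rng.integers(0, 6, size=n_nc)
    nc_pos = rng.integers(NONCODING_START, NONCODING_END, size=n_nc)
    chroms.extend(f"chr{c + 1}" for c in nc_chrom)
    positions.extend(int(p) for p in nc_pos)
    gene_ids.extend([None] * n_nc)

    # substitution class and strand orientation
    cls_idx = rng.choice(6, size=n, p=spec.spectrum_weights)
    pyrimidine = rng.random(n) < 0.5
    refs, alts = [], []
    for k in range(n):
        pyr, pur = _CLASS_PAIRS[CLASSES[cls_idx[k]]]
        ref, alt = pyr if pyrimidine[k] else pur
        refs.append(ref)
        alts.append(alt)

    het = rng.random(n) < spec.het_fraction
    depth = np.maximum(1, rng.negative_binomial(
        spec.depth_dispersion,
        spec.depth_dispersion / (spec.depth_dispersion + spec.depth_mean),
        size=n))
    # integer-valued qualities survive the float32 QUAL column exactly
    quality = np.round(rng.gamma(spec.quality_shape, spec.quality_scale, size=n))

    true_af = np.where(het, 0.5, 1.0)
    if spec.het_allele_sampling:
        alt_reads = rng.binomial(depth, true_af)
    else:
        alt_reads = np.round(true_af * depth).astype(int)
    if spec.af_noise_sd > 0:
        jitter = np.round(rng.normal(0.0, spec.af_noise_sd, size=n) * depth)
        alt_reads = np.clip(alt_reads + jitter.astype(int), 0, depth)
    af = alt_reads / depth

    conseq_choice = rng.choice(3, size=n, p=spec.consequence_weights)
    conseq_names = ("synonymous", "missense", "nonsense")

    rows = []
    seen: set[tuple[str, int]] = set()
    for k in range(n):
        site = (chroms[k], positions[k])
        if site in seen:
            continue  # one call per site per sample
        seen.add(site)
        coding = gene_ids[k] is not None
        rows.append({
            "sample_id": sample_id,
            "chrom": chroms[k],
            "pos": positions[k],
            "ref_allele": refs[k],
            "alt_allele": alts[k],
            "read_depth": int(depth[k]),
            "call_quality": float(quality[k]),
            "allele_fraction": float(af[k]),
            "gene_id": gene_ids[k],
            "consequence": conseq_names[conseq_choice[k]] if coding else "noncoding",
            "zygosity": "heterozygous" if het[k] else "homozygous",
            "is_driver": False,
        })
    return rows


def _assign_site_flags(truth: pd.DataFrame, drivers: Sequence[DriverSpec],
                       spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Known / in-house status is a property of the site, not of the sample.

    Every distinct (chrom, pos, ref, alt) key draws its status once, so the
    same variant observed in two samples is consistently known or novel —
    matching how a positional polymorphism catalogue behaves.  Driver sites
    are forced novel and absent from the in-house set.
    """
    keys = truth[["chrom", "pos", "ref_allele", "alt_allele"]].apply(tuple, axis=1)
    uniq = sorted(set(keys))
    known_draw = rng.random(len(uniq)) >= spec.novel_fraction
    house_draw = rng.random(len(uniq)) < spec.in_house_fraction
    driver_keys = {(_d_chrom(d), d.pos, d.ref_allele, d.alt_allele)
                   for d in drivers}

    known_map: dict[tuple, bool] = {}
    house_map: dict[tuple, bool] = {}
    for i, key in enumerate(uniq):
        if key in driver_keys:
            known_map[key] = False
            house_map[key] = False
        else:
            known_map[key] = bool(known_draw[i])
            # in-house set holds previously seen *novel* calls
            house_map[key] = (not known_draw[i]) and bool(house_draw[i])
    truth = truth.copy()
    truth["known"] = [known_map[k] for k in keys]
    truth["in_house"] = [house_map[k] for k in keys]
    return truth


_DRIVER_CHROM_CACHE: dict[str, str] = {}


def _d_chrom(d: DriverSpec) -> str:
    if d.gene_id not in _DRIVER_CHROM_CACHE:
        for g in make_gene_model():
            _DRIVER_CHROM_CACHE[g.gene_id] = g.chrom
    return _DRIVER_CHROM_CACHE[d.gene_id]


def _inject_drivers(truth: pd.DataFrame, drivers: Sequence[DriverSpec],
                    spec: CohortSpec) -> pd.DataFrame:
    """Force driver variants into their carriers with filter-passing evidence."""
    frames = [truth]
    drop: list[tuple[str, str, int]] = []
    for d in drivers:
        chrom = _d_chrom(d)
        for sample_id in d.carriers:
            drop.append((sample_id, chrom, d.pos))
            af = 1.0 if d.zygosity == "homozygous" else 0.5
            frames.append(pd.DataFrame([{
                "sample_id": sample_id, "chrom": chrom, "pos": d.pos,
                "ref_allele": d.ref_allele, "alt_allele": d.alt_allele,
                "read_depth": 60, "call_quality": 500.0,
                "allele_fraction": af, "gene_id": d.gene_id,
                "consequence": d.consequence, "zygosity": d.zygosity,
                "is_driver": True, "known": False, "in_house": False,
            }]))
    if drop:
        key = truth.set_index(["sample_id", "chrom", "pos"]).index
        truth = truth[~key.isin(drop)]
        frames[0] = truth
    out = pd.concat(frames, ignore_index=True)
    out["known"] = out["known"].astype(bool)
    out["in_house"] = out["in_house"].astype(bool)
    return out


def _in_regions(truth: pd.DataFrame,
                regions: Sequence[tuple[str, int, int]]) -> pd.Series:
    mask = pd.Series(False, index=truth.index)
    for chrom, s, e in regions:
        mask |= ((truth["chrom"] == chrom) & (truth["pos"] >= s)
                 & (truth["pos"] <= e))
    return mask


def _records_from_truth(truth: pd.DataFrame) -> dict[str, list[SnvRecord]]:
    variants: dict[str, list[SnvRecord]] = {}
    for row in truth.itertuples(index=False):
        variants.setdefault(row.sample_id, []).append(SnvRecord(
            sample_id=row.sample_id, chrom=row.chrom, pos=int(row.pos),
            ref_allele=row.ref_allele, alt_allele=row.alt_allele,
            read_depth=int(row.read_depth),
            call_quality=float(row.call_quality),
            allele_fraction=float(row.allele_fraction),
            known_flag=bool(row.known), in_house_flag=bool(row.in_house),
            gene_id=None if row.gene_id in (None, "", float("nan")) or
            (isinstance(row.gene_id, float) and np.isnan(row.gene_id))
            else row.gene_id,
            consequence=row.consequence))
    return variants


# ---------------------------------------------------------------------------
# Array genotypes and CN segments
# ---------------------------------------------------------------------------

def generate_array_genotypes(
    spec: CohortSpec, truth: pd.DataFrame, rng: np.random.Generator,
) -> tuple[list[ArrayGenotype], pd.DataFrame]:
    """Array calls (gold standard = truth genotype) plus WES hom-ref evidence.

    Per sample, a fraction of array sites lands on that sample's variant
    positions (genotype = the truth zygosity) and the rest on fixed
    homozygous-reference panel positions in intergenic space, for which a
    WES depth observation is drawn so the concordance analysis has
    reference-call evidence.
    """
    calls: list[ArrayGenotype] = []
    homref_rows = []
    if spec.array_sites == 0:
        return calls, pd.DataFrame(columns=["sample_id", "chrom", "pos",
                                            "read_depth"])
    n_on_variant = int(round(spec.array_sites * spec.array_variant_fraction))
    panel_pos = np.linspace(NONCODING_START, NONCODING_END,
                            num=max(1, spec.array_sites), dtype=int)
    for sample_id, grp in truth.groupby("sample_id", sort=True):
        if n_on_variant > len(grp):
            raise ValueError(
                f"array_sites on variants ({n_on_variant}) exceeds available "
                f"variant positions ({len(grp)}) for {sample_id}")
        pick = rng.choice(len(grp), size=n_on_variant, replace=False)
        sub = grp.iloc[np.sort(pick)]
        for row in sub.itertuples(index=False):
            calls.append(ArrayGenotype(
                sample_id=sample_id, chrom=row.chrom, pos=int(row.pos),
                genotype="het" if row.zygosity == "heterozygous" else "hom_alt",
                ref_allele=row.ref_allele, alt_allele=row.alt_allele))
        n_ref = spec.array_sites - n_on_variant
        taken = {(r.chrom, int(r.pos)) for r in sub.itertuples(index=False)}
        depth = np.maximum(1, rng.negative_binomial(
            spec.depth_dispersion,
            spec.depth_dispersion / (spec.depth_dispersion + spec.depth_mean),
            size=n_ref))
        for j in range(n_ref):
            chrom = f"chr{(j % 6) + 1}"
            pos = int(panel_pos[j])
            if (chrom, pos) in taken:
                continue
            calls.append(ArrayGenotype(sample_id=sample_id, chrom=chrom,
                                       pos=pos, genotype="hom_ref",
                                       ref_allele="A", alt_allele="G"))
            homref_rows.append({"sample_id": sample_id, "chrom": chrom,
                                "pos": pos, "read_depth": int(depth[j])})
    homref = pd.DataFrame(homref_rows, columns=["sample_id", "chrom", "pos",
                                                "read_depth"])
    return calls, homref


def generate_cn_segments(spec: CohortSpec,
                         cn_events: Sequence[CnEventSpec],
                         genes: Sequence[GeneLocus]) -> list[CnSegment]:
    """Requested CN events carved into a diploid background tiling each chromosome."""
    events_by_sample: dict[str, list[CnEventSpec]] = {}
    for e in cn_events:
        events_by_sample.setdefault(e.sample_id, []).append(e)

    segments: list[CnSegment] = []
    for sample_id in spec.sample_ids:
        per_chrom: dict[str, list[CnEventSpec]] = {}
        for e in events_by_sample.get(sample_id, []):
            per_chrom.setdefault(e.chrom, []).append(e)
        for ci in range(6):
            chrom = f"chr{ci + 1}"
            evs = sorted(per_chrom.get(chrom, []), key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping CN events for {sample_id} on {chrom}")
            cursor = 1
            for e in evs:
                if e.start > cursor:
                    segments.append(CnSegment(sample_id, chrom, cursor,
                                              e.start - 1, 2.0))
                segments.append(CnSegment(sample_id, chrom, e.start, e.end,
                                          e.cn_value))
                cursor = e.end + 1
            if cursor <= CHROM_LENGTH:
                segments.append(CnSegment(sample_id, chrom, cursor,
                                          CHROM_LENGTH, 2.0))
    io.validate_segments(segments)
    return segments


def _cn_truth(cn_events: Sequence[CnEventSpec], genes: Sequence[GeneLocus],
              sample_ids: Sequence[str]) -> pd.DataFrame:
    rows = []
    for e in cn_events:
        for g in genes:
            if g.chrom == e.chrom and e.start <= g.start and g.end <= e.end:
                if e.cn_value > 2.3:
                    status = "amplified"
                elif e.cn_value < 0.7:
                    status = "homozygous_deletion"
                elif e.cn_value < 1.3:
                    status = "one_copy_loss"
                else:
                    status = "neutral"
                rows.append({"sample_id": e.sample_id, "gene_id": g.gene_id,
                             "cn_value": e.cn_value, "status": status})
    return pd.DataFrame(rows, columns=["sample_id", "gene_id", "cn_value",
                                       "status"])


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def _write_bundle(b: CohortBundle) -> None:
    for sample_id, recs in sorted(b.variants.items()):
        io.write_variants(recs, b.vcf_path(sample_id), sample_id)
    io.write_array_genotypes(b.array_genotypes, b.out_dir / "array_genotypes.tsv")
    io.write_depth_sites(b.homref_sites, b.out_dir / "homref_sites.tsv")
    io.write_segments(b.segments, b.out_dir / "segments.tsv")
    io.write_gene_model(b.genes, b.out_dir / "genes.tsv")
    io.write_blacklist(b.blacklist, b.out_dir / "blacklist.bed")
    io.write_site_set(b.known_sites, b.out_dir / "known_sites.tsv")
    io.write_site_set(b.in_house_sites, b.out_dir / "in_house.tsv")
    io.write_catalogue(b.cosmic_mutations, b.out_dir / "cosmic_mutations.tsv")
    pd.DataFrame({"gene_id": b.cosmic_deleted}).to_csv(
        b.out_dir / "cosmic_deleted.tsv", sep="\t", index=False)
    io.write_gene_list(b.curated_genes, b.out_dir / "curated_genes.tsv")
    b.truth_variants.to_csv(b.out_dir / "truth_variants.tsv", sep="\t",
                            index=False)
    b.truth_cn.to_csv(b.out_dir / "truth_cn.tsv", sep="\t", index=False)
    with open(b.out_dir / "cohort_spec.yaml", "w") as fh:
        yaml.safe_dump(_spec_yaml(b.spec), fh, sort_keys=True)


def _spec_yaml(spec: CohortSpec) -> dict:
    d = spec.to_dict()
    d["drivers"] = None if spec.drivers is None else [
        dataclasses.asdict(x) for x in spec.drivers]
    d["cn_events"] = None if spec.cn_events is None else [
        dataclasses.asdict(x) for x in spec.cn_events]
    d["spectrum_weights"] = list(d["spectrum_weights"])
    d["consequence_weights"] = list(d["consequence_weights"])
    return d


def load_spec(path: str | Path) -> CohortSpec:
    """Read a cohort spec back from YAML (inverse of the emitted snapshot)."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if d.get("drivers") is not None:
        d["drivers"] = tuple(DriverSpec(**{**x, "carriers": tuple(x["carriers"])})
                             for x in d["drivers"])
    if d.get("cn_events") is not None:
        d["cn_events"] = tuple(CnEventSpec(**x) for x in d["cn_events"])
    d["spectrum_weights"] = tuple(d["spectrum_weights"])
    d["consequence_weights"] = tuple(d["consequence_weights"])
    return CohortSpec(**d)
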