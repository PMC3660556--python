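import numpy as np
import pytest

from melexo.io_formats import FilterConfig, GeneLocus, SnvRecord
from melexo.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def cfg():
    return FilterConfig()


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """A small six-sample cohort shared across tests (seeded, deterministic)."""
    out = tmp_path_factory.mktemp("cohort")
    return generate_cohort(CohortSpec(seed=11, n_variants_per_sample=2000), out)


@pytest.fixture(scope="session")
def tiny_genes():
    """Two-gene model with introns, for hand-checkable coding queries."""
    return [
        GeneLocus(gene_id="GA", chrom="chr1", start=100, end=999,
                  cds_intervals=((100, 199), (400, 499), (800, 999)),
                  class_tags=frozenset({"classA"})),
        GeneLocus(gene_id="GB", chrom="chr2", start=1000, end=1999,
                  cds_intervals=((1000, 1399), (1600, 1999))),
    ]


def make_snv(sample_id="S1", chrom="chr1", pos=150, ref="C", alt="T",
             depth=30, quality=300.0, af=0.5, known=False, in_house=False,
             gene_id=None, consequence="unannotated"):
    return SnvRecord(sample_id=sample_id, chrom=chrom, pos=pos,
                     ref_allele=ref, alt_allele=alt, read_depth=depth,
                     call_quality=quality, allele_fraction=af,
                     known_flag=known, in_house_flag=in_house,
                     gene_id=gene_id, consequence=consequence)


def random_variants(rng: np.random.Generator, n: int, genes, chrom_pool=None):
    """Randomized variants straddling every filter boundary.

    Positions fall inside and outside CDS; depth, quality and AF are drawn
    around the default thresholds (including the exact boundary values);
    flags and consequences cover all cases.
    """
    bases = np.array(list("ACGT"))
    conseqs = ["synonymous", "missense", "nonsense", "noncoding", "unannotated"]
    out = []
    positions = []
    for g in genes:
        for s, e in g.cds_intervals:
            positions.extend([(g.chrom, s), (g.chrom, e), (g.chrom, (s + e) // 2)])
        positions.append((g.chrom, g.start - 1 if g.start > 1 else g.end + 1))
        positions.append((g.chrom, g.end + 50))
    for i in range(n):
        chrom, pos = positions[rng.integers(len(positions))]
        pos = int(pos + rng.integers(-3, 4))
        if pos < 1:
            pos = 1
        ref, alt = rng.choice(bases, size=2, replace=False)
        depth = int(rng.choice([0, 5, 14, 15, 16, 30, 60]))
        quality = float(rng.choice([0.0, 100.0, 150.0, 150.5, 151.0, 400.0]))
        af = float(rng.choice([0.0, 0.1, 0.2, 0.21, 0.5, 0.84, 0.85, 1.0]))
        conseq = conseqs[rng.integers(len(conseqs))]
        out.append(make_snv(
            sample_id=f"S{rng.integers(3)}", chrom=str(chrom), pos=pos,
            ref=str(ref), alt=str(alt), depth=depth, quality=quality, af=af,
            known=bool(rng.random() < 0.3), in_house=bool(rng.random() < 0.1),
            consequence=conseq))
    return out
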