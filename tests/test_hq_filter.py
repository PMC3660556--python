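"""Filter cascade semantics: boundaries, oracle equivalence, monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from melexo.hq_filter import (
    apply_hq_filter,
    classify_zygosity,
    hq_predicate,
    in_blacklist,
    is_coding,
)
from melexo.io_formats import FilterConfig, GeneLocus

from conftest import make_snv, random_variants


BLACKLIST = [("chr1", 450, 460), ("chr2", 1600, 1700)]


def oracle_pass(v, genes, blacklist, cfg):
    """Independent per-variant restatement of the cascade (linear scans)."""
    if v.known_flag or v.in_house_flag:
        return False
    if v.consequence in ("synonymous", "missense", "nonsense"):
        coding = True
    elif v.consequence == "noncoding":
        coding = False
    else:
        coding = any(v.chrom == g.chrom and s <= v.pos <= e
                     for g in genes for s, e in g.cds_intervals)
    if not coding:
        return False
    if any(v.chrom == c and s <= v.pos <= e for c, s, e in blacklist):
        return False
    return (v.read_depth >= cfg.min_depth
            and v.call_quality > cfg.min_quality
            and v.allele_fraction > cfg.min_af)


# -- boundary semantics ------------------------------------------------------

@pytest.mark.parametrize("depth,quality,af,expected", [
    (15, 151.0, 0.25, True),    # minimum depth is inclusive
    (14, 151.0, 0.25, False),
    (15, 150.0, 0.25, False),   # quality strictly above 150
    (15, 151.0, 0.20, False),   # AF strictly above 20%
    (15, 151.0, 0.2000001, True),
])
def test_threshold_boundaries(cfg, tiny_genes, depth, quality, af, expected):
    v = make_snv(pos=150, depth=depth, quality=quality, af=af,
                 consequence="missense")
    survivors, _ = apply_hq_filter([v], tiny_genes, [], cfg)
    assert bool(survivors) is expected


def test_known_noncoding_blacklist_inhouse_all_reject(cfg, tiny_genes):
    base = dict(pos=450, depth=30, quality=300.0, af=0.5,
                consequence="missense")
    assert apply_hq_filter([make_snv(**base)], tiny_genes, [], cfg)[0]
    for override in ({"known": True}, {"in_house": True},
                     {"consequence": "noncoding"}):
        v = make_snv(**{**base, **override})
        assert not apply_hq_filter([v], tiny_genes, [], cfg)[0]
    # same variant with a blacklist covering its position
    assert not apply_hq_filter([make_snv(**base)], tiny_genes, BLACKLIST, cfg)[0]


def test_empty_input(cfg, tiny_genes):
    survivors, counts = apply_hq_filter([], tiny_genes, [], cfg)
    assert survivors == []
    assert counts["input"] == counts["pass"] == 0


# -- coding / blacklist lookups ----------------------------------------------

def test_is_coding_cds_and_intron(tiny_genes):
    assert is_coding(make_snv(pos=150), tiny_genes) == (True, "GA")
    # intron between two CDS intervals of the same gene
    assert is_coding(make_snv(pos=300), tiny_genes) == (False, None)
    assert is_coding(make_snv(chrom="chr2", pos=1650), tiny_genes) == (True, "GB")


def test_is_coding_matches_bruteforce(tiny_genes):
    rng = np.random.default_rng(5)
    for _ in range(200):
        pos = int(rng.integers(1, 2500))
        chrom = "chr1" if rng.random() < 0.5 else "chr2"
        v = make_snv(chrom=chrom, pos=pos)
        brute = any(chrom == g.chrom and s <= pos <= e
                    for g in tiny_genes for s, e in g.cds_intervals)
        assert is_coding(v, tiny_genes)[0] is brute


def test_blacklist_inclusive_boundaries_and_empty():
    assert in_blacklist(make_snv(pos=450), BLACKLIST)
    assert in_blacklist(make_snv(pos=460), BLACKLIST)
    assert not in_blacklist(make_snv(pos=461), BLACKLIST)
    assert not in_blacklist(make_snv(pos=450), [])
    rng = np.random.default_rng(6)
    for _ in range(200):
        chrom = ["chr1", "chr2"][rng.integers(2)]
        pos = int(rng.integers(1, 2000))
        brute = any(chrom == c and s <= pos <= e for c, s, e in BLACKLIST)
        assert in_blacklist(make_snv(chrom=chrom, pos=pos), BLACKLIST) is brute


# -- zygosity ----------------------------------------------------------------

@pytest.mark.parametrize("af,expected", [
    (1.0, "homozygous"), (0.5, "heterozygous"),
    (0.85, "homozygous"), (0.8499, "heterozygous"),
])
def test_classify_zygosity_cutoff(cfg, af, expected):
    assert classify_zygosity(make_snv(af=af), cfg) == expected


# -- oracle equivalence, conservation, monotonicity --------------------------

def test_cascade_equals_bruteforce_predicate(cfg, tiny_genes):
    rng = np.random.default_rng(17)
    variants = random_variants(rng, 1000, tiny_genes)
    survivors, counts = apply_hq_filter(variants, tiny_genes, BLACKLIST, cfg)
    # compare as multisets of the identifying field tuple
    got_keys = sorted((v.sample_id, v.chrom, v.pos, v.ref_allele,
                       v.alt_allele, v.read_depth) for v in survivors)
    exp_keys = sorted((v.sample_id, v.chrom, v.pos, v.ref_allele,
                       v.alt_allele, v.read_depth) for v in variants
                      if oracle_pass(v, tiny_genes, BLACKLIST, cfg))
    assert got_keys == exp_keys
    for v in variants:
        assert hq_predicate(v, tiny_genes, BLACKLIST, cfg) == \
            oracle_pass(v, tiny_genes, BLACKLIST, cfg)
    # conservation: survivors + per-stage rejections == input
    stage_total = sum(counts[s] for s in
                      ("known", "coding", "blacklist", "in_house",
                       "depth", "quality", "af"))
    assert counts["pass"] + stage_total == counts["input"] == len(variants)


@given(st.integers(min_value=0, max_value=40),
       st.floats(min_value=0, max_value=400, allow_nan=False),
       st.floats(min_value=0.01, max_value=0.8, allow_nan=False))
@settings(max_examples=50, derandomize=True, deadline=None)
def test_tightening_thresholds_never_adds_survivors(min_depth, min_quality, min_af):
    cfg = FilterConfig()
    tight = FilterConfig(min_depth=cfg.min_depth + min_depth % 20,
                         min_quality=cfg.min_quality + min_quality,
                         min_af=min(0.84, cfg.min_af + min_af / 4))
    genes = [GeneLocus(gene_id="G", chrom="chr1", start=1, end=500,
                       cds_intervals=((1, 500),))]
    rng = np.random.default_rng(int(min_depth + min_quality * 7 + min_af * 1000))
    variants = random_variants(rng, 120, genes)
    loose_set, _ = apply_hq_filter(variants, genes, [], cfg)
    tight_set, _ = apply_hq_filter(variants, genes, [], tight)
    loose_keys = {(v.pos, v.sample_id, v.read_depth, v.call_quality,
                   v.allele_fraction) for v in loose_set}
    tight_keys = {(v.pos, v.sample_id, v.read_depth, v.call_quality,
                   v.allele_fraction) for v in tight_set}
    assert tight_keys <= loose_keys


def test_cohort_filter_recovers_truth_exactly(cohort, cfg):
    """Self-consistency: the cascade recovers exactly should_pass_filter."""
    from melexo import io_formats as io
    from melexo.hq_filter import GeneIndex, RegionIndex

    gene_index = GeneIndex(cohort.genes)
    bl = RegionIndex(cohort.blacklist)
    truth = cohort.truth_variants
    expected = {(r.sample_id, r.chrom, int(r.pos))
                for r in truth[truth.should_pass_filter].itertuples()}
    got = set()
    for sample_id, recs in cohort.variants.items():
        survivors, _ = apply_hq_filter(recs, gene_index, bl, cfg)
        got |= {(v.sample_id, v.chrom, v.pos) for v in survivors}
    assert got == expected
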