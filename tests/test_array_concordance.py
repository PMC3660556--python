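"""Concordance stratification, closed-form het behaviour, plateau selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from melexo.array_concordance import (
    PAIR_COLUMNS,
    ConcordanceCurve,
    concordance_by_depth,
    genotype_from_af,
    match_sites,
    select_depth_threshold,
)
from melexo.io_formats import ArrayGenotype, FilterConfig

from conftest import make_snv

#: caller where only all-ref / all-alt read vectors are miscalled at a het site
NAIVE = FilterConfig(min_af=0.01, hom_af_cutoff=1.0)


def _pairs(rows):
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def test_match_sites_pairs_and_exclusions():
    wes = [make_snv(sample_id="S1", pos=100, ref="C", alt="T", depth=20, af=0.5),
           make_snv(sample_id="S1", pos=200, ref="C", alt="T", depth=30, af=1.0)]
    homref = pd.DataFrame([
        {"sample_id": "S1", "chrom": "chr1", "pos": 300, "read_depth": 25},
        {"sample_id": "S1", "chrom": "chr1", "pos": 400, "read_depth": 0},
    ])
    array = [
        ArrayGenotype("S1", "chr1", 100, "het", "C", "T"),
        ArrayGenotype("S1", "chr1", 200, "hom_alt", "C", "A"),  # allele mismatch
        ArrayGenotype("S1", "chr1", 300, "hom_ref", "A", "G"),
        ArrayGenotype("S1", "chr1", 400, "hom_ref", "A", "G"),  # zero coverage
        ArrayGenotype("S1", "chr1", 500, "hom_ref", "A", "G"),  # no WES evidence
    ]
    pairs = match_sites(wes, homref, array)
    assert len(pairs) == 2
    by_pos = pairs.set_index("pos")
    assert by_pos.loc[100, "wes_genotype"] == "het"
    assert by_pos.loc[100, "array_genotype"] == "het"
    assert by_pos.loc[300, "wes_genotype"] == "hom_ref"


def test_error_free_pairs_are_fully_concordant():
    rows = [("S1", "chr1", i, d, g, g)
            for i, (d, g) in enumerate(itertools.product(
                range(1, 6), ("hom_ref", "het", "hom_alt")))]
    curve = concordance_by_depth(_pairs(rows), depth_bins=range(1, 6),
                                 min_sites=1)
    defined = curve.table.dropna(subset=["concordance"])
    assert (defined["concordance"] == 1.0).all()


def test_het_depth4_matches_exhaustive_enumeration():
    """All 2^4 read outcomes at a het site: 14/16 called het by the naive caller."""
    rows = []
    for i, reads in enumerate(itertools.product([0, 1], repeat=4)):
        af = sum(reads) / 4
        rows.append(("S1", "chr1", i, 4, "het", genotype_from_af(af, NAIVE)))
    curve = concordance_by_depth(_pairs(rows), depth_bins=[4], min_sites=1)
    het = curve.stratum("het")
    assert het.loc[0, "concordance"] == pytest.approx(1 - 2 * 0.5 ** 4)  # 0.875


@pytest.mark.parametrize("depth", [2, 4, 6, 8, 10])
def test_het_concordance_matches_closed_form_monte_carlo(depth):
    """Binomial allele sampling at 10,000 sites/bin vs 1 - 2*(1/2)^d, 3 SE."""
    rng = np.random.default_rng(100 + depth)
    n = 10_000
    alt = rng.binomial(depth, 0.5, size=n)
    rows = [("S1", "chr1", i, depth, "het",
             genotype_from_af(k / depth, NAIVE)) for i, k in enumerate(alt)]
    curve = concordance_by_depth(_pairs(rows), depth_bins=[depth], min_sites=1)
    p = 1 - 2 * 0.5 ** depth
    se = math.sqrt(p * (1 - p) / n) if 0 < p < 1 else 1 / n
    got = curve.stratum("het").loc[0, "concordance"]
    assert abs(got - p) <= 3 * se + 1e-12


def test_hom_alt_concordant_at_every_depth_under_binomial_sampling():
    rows = []
    for d in range(1, 11):
        for i in range(5):
            # every sampled read is alt at a hom site
            rows.append(("S1", "chr1", d * 100 + i, d, "hom_alt",
                         genotype_from_af(d / d, NAIVE)))
    curve = concordance_by_depth(_pairs(rows), depth_bins=range(1, 11),
                                 min_sites=1)
    hom = curve.stratum("hom_alt")
    assert (hom["concordance"] == 1.0).all()


def test_small_bins_are_undefined_not_zero():
    rows = [("S1", "chr1", 1, 5, "het", "hom_ref")]  # one discordant site
    curve = concordance_by_depth(_pairs(rows), depth_bins=[5], min_sites=25)
    het = curve.stratum("het")
    assert het.loc[0, "n"] == 1
    assert math.isnan(het.loc[0, "concordance"])


def test_empty_pairs_error():
    with pytest.raises(ValueError):
        concordance_by_depth(_pairs([]))


# -- threshold selection -----------------------------------------------------

def _curve_from_het(concs, start=1):
    rows = []
    for i, c in enumerate(concs):
        d = start + i
        rows.append((d, "het", 1000, c))
        rows.append((d, "hom_ref", 1000, 1.0))
        rows.append((d, "hom_alt", 1000, 1.0))
    return ConcordanceCurve(pd.DataFrame(
        rows, columns=["depth", "stratum", "n", "concordance"]))


def bruteforce_threshold(concs, start, level):
    depths = [start + i for i, c in enumerate(concs) if not math.isnan(c)]
    vals = [c for c in concs if not math.isnan(c)]
    for j, d in enumerate(depths):
        if all(v >= level for v in vals[j:]):
            return d
    return None


def test_sustained_crossing_at_15(cfg):
    """Curve built to cross 90% at depth 15 and stay above -> threshold 15."""
    concs = [0.5 + 0.38 * (d / 14) if d < 15 else 0.92 + 0.001 * d
             for d in range(1, 31)]
    assert select_depth_threshold(_curve_from_het(concs), cfg) == 15


def test_flat_curve_selects_first_bin(cfg):
    assert select_depth_threshold(_curve_from_het([1.0] * 10), cfg) == 1


def test_dip_after_crossing_moves_threshold_past_dip(cfg):
    concs = [0.95] * 5 + [0.85] + [0.95] * 5   # dip at depth 6
    assert select_depth_threshold(_curve_from_het(concs), cfg) == 7


def test_threshold_not_reached_is_none(cfg):
    concs = [0.5] * 10 + [0.89]
    assert select_depth_threshold(_curve_from_het(concs), cfg) is None


def test_threshold_matches_bruteforce_suffix_scan(cfg):
    rng = np.random.default_rng(42)
    for _ in range(200):
        concs = []
        for _ in range(int(rng.integers(1, 25))):
            concs.append(float("nan") if rng.random() < 0.15
                         else float(rng.uniform(0.7, 1.0)))
        got = select_depth_threshold(_curve_from_het(concs), cfg)
        want = bruteforce_threshold(concs, 1, cfg.plateau_level)
        assert got == want, concs


def test_cohort_pair_count_matches_truth_overlap(cohort, cfg):
    pairs = match_sites(
        [v for s in sorted(cohort.variants) for v in cohort.variants[s]],
        cohort.homref_sites, cohort.array_genotypes, cfg)
    # every emitted array site has matching WES evidence by construction
    assert len(pairs) == len(cohort.array_genotypes)
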