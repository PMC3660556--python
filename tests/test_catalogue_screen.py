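"""Catalogue matching, curated-class grouping, recurrence and de-novo screens."""

import numpy as np
import pytest

from melexo.catalogue_screen import (
    annotate,
    annotate_states,
    confirmed_genes,
    driver_frequency,
    find_de_novo,
    find_recurrent,
    match_catalogue,
    samples_with_both,
    screen_curated,
)
from melexo.hq_filter import HqSnv
from melexo.io_formats import CatalogueMutation

from conftest import make_snv


def hq(sample="S1", gene="G1", pos=100, conseq="missense", hom=False,
       ref="C", alt="T", chrom="chr1"):
    rec = make_snv(sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
                   af=1.0 if hom else 0.5, gene_id=gene, consequence=conseq)
    return HqSnv(record=rec, zygosity="homozygous" if hom else "heterozygous")


CAT = [CatalogueMutation("G1", "chr1", 100, "C", "T", "melanoma"),
       CatalogueMutation("G2", "chr1", 500, "A", "G", "lung")]


def test_exact_position_and_allele_matching():
    anns = match_catalogue([hq(pos=100), hq(pos=101), hq(pos=500, ref="A",
                                                         alt="G", gene="G2")],
                           CAT)
    assert anns[0].matched_catalogue_entry.gene_id == "G1"
    assert anns[1].matched_catalogue_entry is None  # 1 bp away
    assert anns[2].matched_catalogue_entry.gene_id == "G2"
    assert confirmed_genes(anns) == {"G1", "G2"}


def test_allele_identity_required_by_default_but_configurable():
    v = hq(pos=100, ref="C", alt="A")  # right position, wrong alt
    strict = match_catalogue([v], CAT)
    loose = match_catalogue([v], CAT, require_allele_match=False)
    assert strict[0].matched_catalogue_entry is None
    assert loose[0].matched_catalogue_entry.gene_id == "G1"


def test_no_spurious_matches_randomized():
    rng = np.random.default_rng(9)
    cat_positions = {(m.chrom, m.pos) for m in CAT}
    variants = [hq(pos=int(rng.integers(1, 1000))) for _ in range(300)]
    anns = match_catalogue(variants, CAT, require_allele_match=False)
    matched = [a for a in anns if a.matched_catalogue_entry is not None]
    unmatched = [a for a in anns if a.matched_catalogue_entry is None]
    assert len(matched) + len(unmatched) == len(variants)  # partition
    for a in matched:
        assert (a.variant.chrom, a.variant.pos) in cat_positions
    for a in unmatched:
        assert (a.variant.chrom, a.variant.pos) not in cat_positions


def test_state_flags():
    anns = annotate_states([
        hq(conseq="nonsense"),
        hq(pos=150, hom=True),
        hq(gene="GD", pos=200), hq(gene="GD", pos=210),  # double-mutated
        hq(gene="GS", pos=300, conseq="synonymous"),
    ])
    assert anns[0].is_truncating and not anns[0].is_homozygous
    assert anns[1].is_homozygous
    assert anns[2].is_double_mutated_gene and anns[3].is_double_mutated_gene
    assert not (anns[4].is_truncating or anns[4].is_homozygous
                or anns[4].is_double_mutated_gene)
    # two NS variants in the same gene but different samples: not double
    anns2 = annotate_states([hq(sample="A", gene="GD", pos=1),
                             hq(sample="B", gene="GD", pos=2)])
    assert not any(a.is_double_mutated_gene for a in anns2)


def test_curated_grouping_multi_class_gene_counts_in_each():
    gene_list = {"G1": frozenset({"MAPK signalling", "Kinases"}),
                 "G2": frozenset({"Kinases"})}
    groups = screen_curated(
        [hq(gene="G1"), hq(gene="G2", pos=200, conseq="synonymous"),
         hq(gene="G3", pos=300)],
        gene_list)
    assert groups["MAPK signalling"]["n_ns"] == 1
    assert groups["Kinases"]["n_ns"] == 1
    assert groups["Kinases"]["n_s"] == 1
    assert "G3" not in groups["Kinases"]["genes"]
    assert screen_curated([hq()], {}) == {}


def test_recurrent_thresholds_and_sorting():
    variants = [hq(sample="A", gene="GX"), hq(sample="B", gene="GX", pos=110),
                hq(sample="A", gene="GY"),
                hq(sample="A", gene="GZ"), hq(sample="B", gene="GZ", pos=120),
                hq(sample="C", gene="GZ", pos=130),
                hq(sample="A", gene="GS", conseq="synonymous"),
                hq(sample="B", gene="GS", conseq="synonymous", pos=140)]
    rows = find_recurrent(variants, min_samples=2)
    assert [r.gene_id for r in rows] == ["GZ", "GX"]  # by sample count, then id
    assert rows[0].n_ns_mutations == 3
    # synonymous-only gene GS never qualifies; single-sample GY excluded
    assert {r.gene_id for r in rows} == {"GX", "GZ"}


def test_recurrent_matches_bruteforce_groupby():
    rng = np.random.default_rng(21)
    variants = [hq(sample=f"S{rng.integers(4)}",
                   gene=f"G{rng.integers(12)}",
                   pos=int(rng.integers(1, 10_000)),
                   conseq=["missense", "nonsense",
                           "synonymous"][rng.integers(3)])
                for _ in range(400)]
    rows = find_recurrent(variants, min_samples=2)
    brute: dict[str, set] = {}
    counts: dict[str, int] = {}
    for v in variants:
        if v.consequence == "synonymous":
            continue
        brute.setdefault(v.gene_id, set()).add(v.sample_id)
        counts[v.gene_id] = counts.get(v.gene_id, 0) + 1
    expected = sorted(((g, frozenset(s), counts[g])
                       for g, s in brute.items() if len(s) >= 2),
                      key=lambda t: (-len(t[1]), t[0]))
    assert [(r.gene_id, r.mutated_samples, r.n_ns_mutations)
            for r in rows] == expected


def test_de_novo_excludes_catalogue_and_curated_genes():
    variants = [hq(sample="A", gene=g, pos=p) for g, p in
                [("KNOWN1", 10), ("CUR1", 20), ("NEW1", 30)]] + \
               [hq(sample="B", gene=g, pos=p + 1) for g, p in
                [("KNOWN1", 10), ("CUR1", 20), ("NEW1", 30)]]
    rows = find_de_novo(variants, cosmic_genes={"KNOWN1"},
                        curated_genes={"CUR1"}, min_samples=2)
    assert [r.gene_id for r in rows] == ["NEW1"]
    out = {r.gene_id for r in rows}
    assert out.isdisjoint({"KNOWN1"}) and out.isdisjoint({"CUR1"})


def test_driver_frequency_floor_percentages():
    variants = [hq(sample=s, gene="BRAF") for s in
                ("Me01", "Me04", "Me08", "Me12")]
    assert driver_frequency(variants, "BRAF", 6) == (pytest.approx(4 / 6), 66)
    assert driver_frequency(variants[:1], "BRAF", 6) == (pytest.approx(1 / 6), 16)
    assert driver_frequency([], "BRAF", 6) == (0.0, 0)
    with pytest.raises(ValueError):
        driver_frequency(variants, "BRAF", 0)


def test_mutual_exclusivity_is_computable():
    variants = [hq(sample="A", gene="BRAF"), hq(sample="B", gene="BRAF"),
                hq(sample="C", gene="NRAS"),
                hq(sample="D", gene="BRAF"), hq(sample="D", gene="NRAS", pos=7)]
    assert samples_with_both(variants, "BRAF", "NRAS") == {"D"}


def test_annotate_combines_catalogue_and_curated_tags():
    anns = annotate([hq(pos=100)], catalogue=CAT,
                    gene_list={"G1": frozenset({"MAPK signalling"})})
    assert anns[0].matched_catalogue_entry.gene_id == "G1"
    assert anns[0].curated_class_tags == {"MAPK signalling"}
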