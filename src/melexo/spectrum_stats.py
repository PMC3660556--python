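"""Strand-collapsed substitution spectrum, NS/S ratios, per-sample summaries.

A substitution and its reverse complement are the same mutational event read
from opposite strands, so the 12 ordered single-base changes collapse to 6
classes, keyed here by the pyrimidine-reference member and displayed with
both members (e.g. "C>T/G>A").  Dominance of C>T/G>A transitions is the
classical UV-exposure signature in cutaneous melanoma.

The NS/S ratio (non-synonymous, i.e. missense plus nonsense, over synonymous
counts) is a coarse selection indicator: values near 2 match the expectation
for unselected passenger mutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import BASES

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: The six collapsed substitution classes, pyrimidine member first.
CLASSES = ("C>T/G>A", "C>A/G>T", "C>G/G>C", "T>C/A>G", "T>A/A>T", "T>G/A>C")


def substitution_class(ref: str, alt: str) -> str:
    """Collapsed class label for a single-base substitution.

    The substitution is flipped to its reverse complement when the reference
    base is a purine, so (C,T) and (G,A) both map to "C>T/G>A".
    """
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"invalid base in substitution {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in ("C", "T"):
        label = f"{ref}>{alt}/{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}"
    else:
        label = f"{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}/{ref}>{alt}"
    assert label in CLASSES
    return label


@dataclass(frozen=True)
class SpectrumCounts:
    """Counts per collapsed substitution class; counts always sum to total."""

    counts: Mapping[str, int]
    total: int

    def __post_init__(self) -> None:
        if set(self.counts) != set(CLASSES):
            raise ValueError("counts must cover exactly the 6 collapsed classes")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative class count")
        if sum(self.counts.values()) != self.total:
            raise ValueError("class counts do not sum to total")

    def fraction(self, label: str) -> float:
        return self.counts[label] / self.total if self.total else 0.0


def spectrum(variants: Iterable) -> SpectrumCounts:
    """Count variants (anything with ref_allele/alt_allele) per collapsed class."""
    counts = {c: 0 for c in CLASSES}
    total = 0
    for v in variants:
        counts[substitution_class(v.ref_allele, v.alt_allele)] += 1
        total += 1
    return SpectrumCounts(counts=counts, total=total)


def ns_s_ratio(n_ns: int, n_s: int, decimals: int = 2) -> float | None:
    """NS/S ratio rounded to ``decimals``; None (undefined) when n_s is zero.

    Whole-dataset and per-sample ratios are conventionally printed with two
    decimals; functional-class ratios with one.
    """
    if n_ns < 0 or n_s < 0:
        raise ValueError("counts must be non-negative")
    if n_s == 0:
        return None
    return round(n_ns / n_s, decimals)


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample variant counts at each cascade stage plus the NS/S ratio."""

    sample_id: str
    n_total_snvs: int
    n_novel: int
    n_novel_coding: int
    n_hq: int
    n_nonsynonymous: int
    n_synonymous: int
    ns_s_ratio: float | None

    def __post_init__(self) -> None:
        if self.n_hq != self.n_nonsynonymous + self.n_synonymous:
            raise ValueError(
                f"{self.sample_id}: HQ count {self.n_hq} != NS {self.n_nonsynonymous}"
                f" + S {self.n_synonymous}")
        if not (self.n_hq <= self.n_novel_coding <= self.n_novel <= self.n_total_snvs):
            raise ValueError(f"{self.sample_id}: stage counts are not nested")


def build_summary(
    per_sample: Mapping[str, Mapping[str, int]],
) -> tuple[list[SampleSummary], dict[str, float]]:
    """Assemble per-sample summaries and cohort aggregates.

    ``per_sample`` maps sample id to a dict with keys total, novel,
    novel_coding, ns, s (counts at each stage).  Aggregates are column sums
    plus per-sample means (rounded to integer, as conventionally printed) and
    the whole-dataset NS/S ratio.
    """
    summaries = []
    for sample_id in per_sample:
        c = per_sample[sample_id]
        summaries.append(SampleSummary(
            sample_id=sample_id,
            n_total_snvs=int(c["total"]),
            n_novel=int(c["novel"]),
            n_novel_coding=int(c["novel_coding"]),
            n_hq=int(c["ns"]) + int(c["s"]),
            n_nonsynonymous=int(c["ns"]),
            n_synonymous=int(c["s"]),
            ns_s_ratio=ns_s_ratio(int(c["ns"]), int(c["s"])),
        ))
    n = len(summaries)
    total_ns = sum(s.n_nonsynonymous for s in summaries)
    total_s = sum(s.n_synonymous for s in summaries)
    aggregates = {
        "n_samples": n,
        "total_snvs": sum(s.n_total_snvs for s in summaries),
        "total_novel": sum(s.n_novel for s in summaries),
        "total_novel_coding": sum(s.n_novel_coding for s in summaries),
        "total_hq": sum(s.n_hq for s in summaries),
        "total_ns": total_ns,
        "total_s": total_s,
        "mean_ns": round(total_ns / n) if n else 0,
        "mean_s": round(total_s / n) if n else 0,
        "ns_s_ratio": ns_s_ratio(total_ns, total_s),
    }
    return summaries, aggregates


def summary_table(summaries: Sequence[SampleSummary]) -> pd.DataFrame:
    rows = [{
        "sample_id": s.sample_id,
        "n_total_snvs": s.n_total_snvs,
        "n_novel": s.n_novel,
        "n_novel_coding": s.n_novel_coding,
        "n_hq": s.n_hq,
        "n_nonsynonymous": s.n_nonsynonymous,
        "n_synonymous": s.n_synonymous,
        "ns_s_ratio": "NA" if s.ns_s_ratio is None else s.ns_s_ratio,
    } for s in summaries]
    return pd.DataFrame(rows, columns=[
        "sample_id", "n_total_snvs", "n_novel", "n_novel_coding", "n_hq",
        "n_nonsynonymous", "n_synonymous", "ns_s_ratio"])


def spectrum_table(per_sample_spectra: Mapping[str, SpectrumCounts]) -> pd.DataFrame:
    rows = []
    for sample_id, spec in per_sample_spectra.items():
        for label in CLASSES:
            rows.append({
                "sample_id": sample_id,
                "substitution_class": label,
                "count": spec.counts[label],
                "fraction": round(spec.fraction(label), 6),
            })
    return pd.DataFrame(rows, columns=["sample_id", "substitution_class",
                                       "count", "fraction"])
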