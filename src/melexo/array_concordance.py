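"""WES vs SNP-array genotype concordance as a function of read depth.

The array call is treated as the gold standard.  The WES genotype at each
array site is derived from the allele fraction with a threshold caller:
hom_ref when AF <= min_af, hom_alt when AF >= hom_af_cutoff, het otherwise;
array sites with no variant call but with read coverage count as WES hom_ref
evidence.  Concordance is stratified by the array genotype (hom_ref / het /
hom_alt) and binned by integer read depth.  Homozygous strata stay near 100%
at any depth, while the heterozygous stratum climbs with depth — the depth at
which it sustains a target level (default 90%) is taken as the minimum read
depth for SNV calling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ArrayGenotype, FilterConfig, SnvRecord

logger = logging.getLogger("melexo")

STRATA = ("hom_ref", "het", "hom_alt")

PAIR_COLUMNS = ["sample_id", "chrom", "pos", "read_depth",
                "array_genotype", "wes_genotype"]


def genotype_from_af(allele_fraction: float, cfg: FilterConfig = FilterConfig()) -> str:
    """Threshold genotype caller on the non-reference allele fraction."""
    if allele_fraction <= cfg.min_af:
        return "hom_ref"
    if allele_fraction >= cfg.hom_af_cutoff:
        return "hom_alt"
    return "het"


@dataclass(frozen=True)
class ConcordanceCurve:
    """Per-depth, per-stratum concordance with site counts.

    ``table`` has columns depth / stratum / n / concordance; bins with fewer
    than the configured minimum number of sites carry concordance NaN
    (undefined), never 0.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        depths = self.table["depth"].unique()
        if not np.all(np.diff(np.sort(depths)) > 0):
            raise ValueError("depth bins must be strictly increasing")
        conc = self.table["concordance"].dropna()
        if len(conc) and not ((conc >= 0) & (conc <= 1)).all():
            raise ValueError("concordance outside [0,1]")

    def stratum(self, name: str) -> pd.DataFrame:
        return (self.table[self.table["stratum"] == name]
                .sort_values("depth").reset_index(drop=True))


def match_sites(
    wes_variants: Sequence[SnvRecord],
    homref_sites: pd.DataFrame,
    array_calls: Sequence[ArrayGenotype],
    cfg: FilterConfig = FilterConfig(),
) -> pd.DataFrame:
    """Pair each array site with the WES evidence covering it.

    ``homref_sites`` is a frame (sample_id, chrom, pos, read_depth) of
    covered positions without a variant call, standing in for the reference
    calls a VCF omits.  Array sites with no WES coverage produce no pair;
    sites where WES and array disagree on the ref/alt alleles are excluded
    and counted in the log.
    """
    var_by_site: dict[tuple[str, str, int], SnvRecord] = {}
    for v in wes_variants:
        var_by_site[(v.sample_id, v.chrom, v.pos)] = v
    homref = {(r.sample_id, r.chrom, int(r.pos)): int(r.read_depth)
              for r in homref_sites.itertuples(index=False)}

    rows = []
    n_allele_mismatch = 0
    for a in array_calls:
        key = (a.sample_id, a.chrom, a.pos)
        v = var_by_site.get(key)
        if v is not None:
            if (v.ref_allele, v.alt_allele) != (a.ref_allele, a.alt_allele):
                n_allele_mismatch += 1
                continue
            rows.append((a.sample_id, a.chrom, a.pos, v.read_depth,
                         a.genotype, genotype_from_af(v.allele_fraction, cfg)))
        elif key in homref and homref[key] > 0:
            rows.append((a.sample_id, a.chrom, a.pos, homref[key],
                         a.genotype, "hom_ref"))
    if n_allele_mismatch:
        logger.info("excluded %d array site(s) with mismatching alleles",
                    n_allele_mismatch)
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def concordance_by_depth(
    pairs: pd.DataFrame,
    depth_bins: Sequence[int] = tuple(range(1, 51)),
    min_sites: int = 25,
) -> ConcordanceCurve:
    """Per-stratum fraction of agreeing pairs at each integer depth bin.

    Depths above the last bin are clamped into it; depths below the first are
    dropped.  Bins holding fewer than ``min_sites`` pairs are reported with
    concordance NaN (undefined) so that noisy tail estimates never enter the
    threshold selection.
    """
    if len(pairs) == 0:
        raise ValueError("no pairs to evaluate")
    bins = sorted(int(b) for b in depth_bins)
    if not bins:
        raise ValueError("empty depth_bins")
    bin_set = set(bins)
    depth = pairs["read_depth"].to_numpy()
    clamped = np.minimum(depth, bins[-1])
    rows = []
    df = pairs.assign(_bin=clamped)
    df = df[df["_bin"] >= bins[0]]
    df = df[df["_bin"].isin(bin_set)]
    agree = df["array_genotype"] == df["wes_genotype"]
    for d in bins:
        at_d = df["_bin"] == d
        for stratum in STRATA:
            mask = at_d & (df["array_genotype"] == stratum)
            n = int(mask.sum())
            conc = float(agree[mask].mean()) if n >= min_sites else math.nan
            rows.append((d, stratum, n, conc))
    return ConcordanceCurve(pd.DataFrame(
        rows, columns=["depth", "stratum", "n", "concordance"]))


def select_depth_threshold(curve: ConcordanceCurve,
                           cfg: FilterConfig = FilterConfig()) -> int | None:
    """Smallest depth whose het concordance stays at/above the plateau level.

    A "plateau" is operationalized as a sustained crossing: the selected
    depth d has het concordance >= plateau_level at d and at every defined
    bin above d.  Returns None when no such depth exists (threshold not
    reached).
    """
    het = curve.stratum("het")
    defined = het.dropna(subset=["concordance"])
    if defined.empty:
        return None
    ok = defined["concordance"].to_numpy() >= cfg.plateau_level
    # last index where the level is NOT met; threshold is the next defined bin
    failing = np.nonzero(~ok)[0]
    if failing.size == 0:
        return int(defined["depth"].iloc[0])
    last_fail = failing[-1]
    if last_fail == len(defined) - 1:
        return None
    return int(defined["depth"].iloc[last_fail + 1])
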