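"""Panel construction and per-site QC filters.

Builds the three panel analogues compared throughout the package from one
genotype set:

* a *dispersed genome* panel: evenly spread coordinate stripes (the first
  ``take`` bp of every full ``stretch`` bp window, telomeric ends excluded),
* an *exome-like* panel: variants inside coverage-qualified target regions,
* an *array-like* panel: variants at positions drawn from a site list
  (e.g. an ascertained, AIM-enriched manifest).

Per-site QC mirrors common cohort practice: symmetric carrier-count filtering
on both alleles and an inbreeding-coefficient (Hardy-Weinberg excess
heterozygosity) filter.  All filters only change site membership, never
dosage values, and are idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, RegionSet, SEX_CHROM_LABELS

__all__ = [
    "GRCH37_AUTOSOME_LENGTHS",
    "CoverageSummary",
    "SiteQCStats",
    "qualify_regions",
    "genome_scheme_regions",
    "intersect_variants",
    "select_sites",
    "filter_carriers",
    "site_inbreeding",
    "filter_inbreeding",
]

#: GRCh37 / hg19 primary-assembly autosome lengths (bp).
GRCH37_AUTOSOME_LENGTHS: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566,
}


@dataclass
class CoverageSummary:
    """Per-region depth summary: (chrom, start, end, min_cov, mapq0).

    ``min_cov`` is the minimum coverage across all cohort samples in the
    region; ``mapq0`` the count of mapping-quality-zero reads (reads mappable
    to multiple genomic locations).  Coordinates 0-based half-open.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        cols = ["chrom", "start", "end", "min_cov", "mapq0"]
        self.table = pd.DataFrame(self.table, columns=cols).copy()
        for c in cols[1:]:
            self.table[c] = self.table[c].astype(np.int64)
        if (self.table[["min_cov", "mapq0"]] < 0).to_numpy().any():
            raise ValueError("coverage/MAPQ0 counts must be >= 0")

    @classmethod
    def read_tsv(cls, path) -> "CoverageSummary":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "min_cov", "mapq0"],
                         dtype={0: str})
        return cls(df)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class SiteQCStats:
    """Per-site QC statistics: carrier counts, genotype counts, inbreeding F."""

    table: pd.DataFrame  # columns: chrom,pos,ref_carriers,alt_carriers,hom_ref,het,hom_alt,f_site


def qualify_regions(
    cov: CoverageSummary,
    min_cov: int = 10,
    max_mapq0: int = 0,
    exclude_sex: bool = True,
) -> RegionSet:
    """Keep high-confidence regions: coverage strictly above ``min_cov`` in
    every sample, at most ``max_mapq0`` multi-mappable reads, and (by default)
    no sex chromosomes."""
    t = cov.table
    keep = (t["min_cov"] > min_cov) & (t["mapq0"] <= max_mapq0)
    if exclude_sex:
        keep &= ~t["chrom"].astype(str).isin(SEX_CHROM_LABELS)
    sub = t.loc[keep, ["chrom", "start", "end"]]
    return RegionSet(sub)


def genome_scheme_regions(
    chrom_lengths: dict[str, int] | None = None,
    telomere_excl: int = 5_000_000,
    stretch: int = 10_000,
    take: int = 258,
) -> RegionSet:
    """Evenly dispersed genome panel coordinates.

    Per chromosome of length L the usable span is [telomere_excl,
    L - telomere_excl); the span is tiled into consecutive full ``stretch`` bp
    windows (a trailing partial window is discarded) and each window
    contributes its first ``take`` bp as one region.  Chromosomes shorter than
    twice the telomere exclusion contribute nothing.
    """
    if take > stretch:
        raise ValueError("take must not exceed stretch")
    if chrom_lengths is None:
        chrom_lengths = GRCH37_AUTOSOME_LENGTHS
    rows: list[tuple[str, int, int]] = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        span = length - 2 * telomere_excl
        if span <= 0:
            continue
        n_full = span // stretch
        starts = telomere_excl + stretch * np.arange(n_full, dtype=np.int64)
        rows.extend((chrom, int(s), int(s) + take) for s in starts)
    return RegionSet.from_tuples(rows)


def intersect_variants(g: GenotypeMatrix, rs: RegionSet) -> GenotypeMatrix:
    """Keep sites whose position falls inside the region set (order kept)."""
    if g.n_sites == 0 or len(rs) == 0:
        return g.take_sites(np.empty(0, dtype=np.intp))
    mask = rs.contains_positions(g.sites["chrom"].to_numpy(),
                                 g.sites["pos"].to_numpy())
    return g.take_sites(np.flatnonzero(mask))


def select_sites(g: GenotypeMatrix, sites: set[tuple[str, int]]) -> GenotypeMatrix:
    """Keep exact (chrom, pos) matches against a site list.

    Matching is by coordinate only: array manifests can be strand-flipped, so
    allele identity is deliberately not required.
    """
    keys = list(zip(g.sites["chrom"].astype(str), g.sites["pos"].astype(int)))
    keep = np.fromiter((k in sites for k in keys), count=len(keys), dtype=bool)
    return g.take_sites(np.flatnonzero(keep))


def filter_carriers(g: GenotypeMatrix, min_individuals: int = 10) -> GenotypeMatrix:
    """Symmetric rare-allele filter.

    A site is kept only if BOTH alleles are carried by at least
    ``min_individuals`` individuals: alt carriers have dosage > 0, ref
    carriers dosage < 2 (missing genotypes are excluded from both counts).
    The lower arm removes rare variants, the upper arm near-fixed alternate
    alleles (reference-error candidates).
    """
    d = g.dosages
    obs = d != MISSING
    alt_carriers = ((d > 0) & obs).sum(axis=0)
    ref_carriers = ((d < 2) & obs).sum(axis=0)
    keep = (alt_carriers >= min_individuals) & (ref_carriers >= min_individuals)
    return g.take_sites(np.flatnonzero(keep))


def site_inbreeding(g: GenotypeMatrix) -> SiteQCStats:
    """Per-site inbreeding coefficient F = 1 - observed het / expected het.

    Expected heterozygosity is 2 p (1-p) with p estimated from non-missing
    dosages.  Monomorphic sites (expected het 0) get F = 0 by convention.
    Excess heterozygosity yields negative F (the Hardy-Weinberg violation
    signature of spurious calls in a cohort of unrelated individuals).
    """
    d = g.dosages
    obs = d != MISSING
    n_obs = obs.sum(axis=0).astype(float)
    hom_ref = ((d == 0) & obs).sum(axis=0)
    het = ((d == 1) & obs).sum(axis=0)
    hom_alt = ((d == 2) & obs).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, np.where(obs, d, 0).sum(axis=0) / (2 * n_obs), 0.0)
        exp_het = 2 * p * (1 - p)
        obs_het = np.where(n_obs > 0, het / n_obs, 0.0)
        f_site = np.where(exp_het > 0, 1.0 - obs_het / exp_het, 0.0)
    table = pd.DataFrame({
        "chrom": g.sites["chrom"], "pos": g.sites["pos"],
        "ref_carriers": ((d < 2) & obs).sum(axis=0),
        "alt_carriers": ((d > 0) & obs).sum(axis=0),
        "hom_ref": hom_ref, "het": het, "hom_alt": hom_alt,
        "f_site": f_site,
    })
    return SiteQCStats(table=table)


def filter_inbreeding(g: GenotypeMatrix, min_f: float = -0.5) -> GenotypeMatrix:
    """Drop sites with inbreeding coefficient below ``min_f`` (excess het)."""
    f = site_inbreeding(g).table["f_site"].to_numpy()
    return g.take_sites(np.flatnonzero(f >= min_f))
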