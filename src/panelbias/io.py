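"""Genotype data model and readers/writers for VCF, BED, TSV site lists and labels.

The central container is :class:`GenotypeMatrix`: a samples x sites matrix of
diploid alternate-allele dosages (0/1/2, ``-1`` for missing) together with the
variant coordinates and a population label per sample.  Phase is discarded on
input; none of the downstream statistics use it.

Coordinate conventions: VCF positions are 1-based; BED intervals (and
:class:`RegionSet` internally) are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

SEX_CHROM_LABELS = {"X", "Y", "chrX", "chrY"}

_BASES = {"A", "C", "G", "T"}


class VcfFormatError(ValueError):
    """Raised for malformed VCF input."""


class LabelError(ValueError):
    """Raised when sample/population labels do not cover the genotype data."""


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP alt-allele dosage matrix with metadata.

    Parameters
    ----------
    dosages
        int8 array of shape (n_samples, n_sites) with values in {0, 1, 2}
        or ``MISSING`` (-1).
    sites
        DataFrame with columns ``chrom, pos, ref, alt, id``; ``pos`` 1-based,
        strictly increasing within each chromosome.
    samples
        Ordered sample identifiers.
    populations
        Population label per sample (aligned with ``samples``).
    """

    dosages: np.ndarray
    sites: pd.DataFrame
    samples: list[str]
    populations: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x sites)")
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("dosage rows != number of samples")
        if self.dosages.shape[1] != len(self.sites):
            raise ValueError("dosage columns != number of sites")
        if len(self.populations) != len(self.samples):
            raise LabelError("every sample needs exactly one population label")
        self.sites = self.sites.reset_index(drop=True)

    # -- basic queries ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    @property
    def pop_of(self) -> dict[str, str]:
        return dict(zip(self.samples, self.populations))

    def pop_indices(self) -> dict[str, np.ndarray]:
        """Map population label -> array of sample row indices."""
        pops: dict[str, list[int]] = {}
        for i, p in enumerate(self.populations):
            pops.setdefault(p, []).append(i)
        return {p: np.asarray(ix, dtype=np.intp) for p, ix in pops.items()}

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    # -- subsetting ---------------------------------------------------------

    def take_sites(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        """Subset to the given site indices (order preserved as given)."""
        index = np.asarray(index, dtype=np.intp)
        return GenotypeMatrix(
            dosages=self.dosages[:, index].copy(),
            sites=self.sites.iloc[index].reset_index(drop=True),
            samples=list(self.samples),
            populations=list(self.populations),
        )

    def take_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=np.intp)
        return GenotypeMatrix(
            dosages=self.dosages[index, :].copy(),
            sites=self.sites.copy(),
            samples=[self.samples[i] for i in index],
            populations=[self.populations[i] for i in index],
        )

    def drop_sex_chromosomes(self) -> "GenotypeMatrix":
        keep = ~self.sites["chrom"].astype(str).isin(SEX_CHROM_LABELS)
        return self.take_sites(np.flatnonzero(keep.to_numpy()))

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.dosages, other.dosages)
            and self.sites.equals(other.sites)
            and self.samples == other.samples
            and self.populations == other.populations
        )


# ---------------------------------------------------------------------------
# RegionSet
# ---------------------------------------------------------------------------

@dataclass
class RegionSet:
    """Ordered genomic intervals, 0-based half-open, normalized on creation.

    Normalization sorts by (chrom, start) and merges overlapping or abutting
    intervals on the same chromosome.
    """

    intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"])
    )

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.intervals, columns=["chrom", "start", "end"]).copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(
                f"interval start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        self.intervals = self._normalize(df)

    @staticmethod
    def _normalize(df: pd.DataFrame) -> pd.DataFrame:
        if df.empty:
            return df.reset_index(drop=True)
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        out: list[tuple[str, int, int]] = []
        for chrom, sub in df.groupby("chrom", sort=True):
            cur_start = cur_end = None
            for s, e in zip(sub["start"], sub["end"]):
                if cur_start is None:
                    cur_start, cur_end = s, e
                elif s <= cur_end:
                    cur_end = max(cur_end, e)
                else:
                    out.append((chrom, cur_start, cur_end))
                    cur_start, cur_end = s, e
            out.append((chrom, cur_start, cur_end))
        return pd.DataFrame(out, columns=["chrom", "start", "end"])

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[str, int, int]]) -> "RegionSet":
        return cls(pd.DataFrame(list(tuples), columns=["chrom", "start", "end"]))

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.intervals.reset_index(drop=True).equals(
            other.intervals.reset_index(drop=True)
        )

    def total_length(self) -> int:
        if self.intervals.empty:
            return 0
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    def drop_sex_chromosomes(self) -> "RegionSet":
        keep = ~self.intervals["chrom"].astype(str).isin(SEX_CHROM_LABELS)
        df = self.intervals[keep]
        return RegionSet(df)

    def contains_positions(self, chroms: Sequence[str], pos_1based: np.ndarray) -> np.ndarray:
        """Boolean mask: does 1-based position fall inside any interval?

        A 1-based position p lies in a 0-based half-open interval [s, e)
        iff s < p <= e.
        """
        pos = np.asarray(pos_1based, dtype=np.int64)
        mask = np.zeros(len(pos), dtype=bool)
        chroms = np.asarray(chroms, dtype=object)
        for chrom, sub in self.intervals.groupby("chrom", sort=False):
            sel = chroms == chrom
            if not sel.any():
                continue
            p = pos[sel]
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            # intervals are sorted & disjoint: binary search on starts
            idx = np.searchsorted(starts, p - 1, side="right") - 1
            ok = (idx >= 0) & (p <= ends[np.clip(idx, 0, len(ends) - 1)])
            mask[np.flatnonzero(sel)[ok]] = True
        return mask


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    pass_only: bool = False,
    snps_only: bool = True,
    exclude_sex: bool = True,
    labels: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are always dropped (with a logged count); records
    failing FILTER are dropped when ``pass_only``; non-SNP records are dropped
    when ``snps_only``.  Phased and unphased genotypes are treated identically;
    half-calls become missing.  Sample population labels default to
    ``"unknown"`` when no label map is supplied.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise VcfFormatError(f"{path}: no samples / GT fields")

    rows: list[tuple[str, int, str, str, str]] = []
    dosage_cols: list[np.ndarray] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        if snps_only and not (
            len(var.REF) == 1 and len(var.ALT[0]) == 1
            and var.REF in _BASES and var.ALT[0] in _BASES
        ):
            continue
        if pass_only and var.FILTER is not None:  # cyvcf2: None == PASS/'.'
            continue
        if exclude_sex and var.CHROM in SEX_CHROM_LABELS:
            continue
        # gts012: 0/1/2 dosage, 3 = unknown
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        dosage_cols.append(gt)
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0],
                     var.ID if var.ID else f"{var.CHROM}:{var.POS}"))
    if n_multi:
        logger.info("read_vcf: dropped %d multi-allelic records", n_multi)

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "id"])
    dosages = (
        np.column_stack(dosage_cols)
        if dosage_cols
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    if labels is not None:
        missing = [s for s in samples if s not in labels]
        if missing:
            raise LabelError(f"samples missing from label map: {missing}")
        pops = [labels[s] for s in samples]
    else:
        pops = ["unknown"] * len(samples)
    return GenotypeMatrix(dosages=dosages, sites=sites, samples=samples, populations=pops)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as a minimal VCFv4.2 (GT-only) text file."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(g.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        sites = g.sites
        for j in range(g.n_sites):
            row = sites.iloc[j]
            gts = "\t".join(_GT_STR[int(d)] for d in g.dosages[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> RegionSet:
    """Read a 3+ column BED file into a normalized RegionSet."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"],
                         dtype={0: str})
    except pd.errors.EmptyDataError:
        return RegionSet()
    return RegionSet(df)


def write_bed(rs: RegionSet, path: str | Path) -> None:
    rs.intervals.to_csv(path, sep="\t", header=False, index=False)


def read_site_list(path: str | Path) -> set[tuple[str, int]]:
    """Read a 2-column TSV (chrom, 1-based position); duplicates collapsed."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1], names=["chrom", "pos"], dtype={0: str})
    except pd.errors.EmptyDataError:
        return set()
    return set(zip(df["chrom"], df["pos"].astype(int)))


def write_site_list(sites: Iterable[tuple[str, int]], path: str | Path) -> None:
    df = pd.DataFrame(sorted(sites), columns=["chrom", "pos"])
    df.to_csv(path, sep="\t", header=False, index=False)


def read_pop_labels(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping sample id -> population label."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1], names=["sample", "population"], dtype=str)
    return dict(zip(df["sample"], df["population"]))


def write_pop_labels(g: GenotypeMatrix, path: str | Path) -> None:
    pd.DataFrame({"sample": g.samples, "population": g.populations}).to_csv(
        path, sep="\t", header=False, index=False
    )


def attach_labels(g: GenotypeMatrix, labels: Mapping[str, str]) -> GenotypeMatrix:
    """Attach population labels; error if any sample is missing a label."""
    missing = [s for s in g.samples if s not in labels]
    if missing:
        raise LabelError(f"samples missing from label map: {missing}")
    return GenotypeMatrix(
        dosages=g.dosages.copy(),
        sites=g.sites.copy(),
        samples=list(g.samples),
        populations=[labels[s] for s in g.samples],
    )


# ---------------------------------------------------------------------------
# PED/MAP export (interoperability; dosage-faithful, dialect not guaranteed)
# ---------------------------------------------------------------------------

def write_ped_map(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Export as space-separated PED/MAP (one line per sample).

    Alleles are written as REF/ALT bases; missing genotypes as "0 0".
    """
    prefix = Path(prefix)
    sites = g.sites
    with open(f"{prefix}.map", "w") as fh:
        for j in range(g.n_sites):
            r = sites.iloc[j]
            fh.write(f"{r['chrom']} {r['id']} 0 {r['pos']}\n")
    ref = sites["ref"].to_numpy()
    alt = sites["alt"].to_numpy()
    with open(f"{prefix}.ped", "w") as fh:
        for i, sample in enumerate(g.samples):
            alleles: list[str] = []
            for j, d in enumerate(g.dosages[i]):
                if d == MISSING:
                    alleles.append("0 0")
                elif d == 0:
                    alleles.append(f"{ref[j]} {ref[j]}")
                elif d == 1:
                    alleles.append(f"{ref[j]} {alt[j]}")
                else:
                    alleles.append(f"{alt[j]} {alt[j]}")
            fh.write(f"{g.populations[i]} {sample} 0 0 0 -9 " + " ".join(alleles) + "\n")
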