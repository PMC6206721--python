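"""Structured-population genotype simulation.

The generator emulates the ingredients a panel-comparison study needs:

* a two-level population hierarchy (super-populations containing populations)
  with Balding-Nichols drift on every branch,
* admixed populations whose allele copies are drawn from source populations,
* LD blocks (runs of near-identical marker columns),
* uniform ("genome-like") versus clustered ("exome-like") marker coordinates,
* ascertained site lists enriched for ancestry-informative markers (AIMs).

Under the Balding-Nichols model a branch with drift parameter F transforms a
parent allele frequency p into a Beta(p(1-F)/F, (1-p)(1-F)/F) draw, whose
mean is p and whose variance is F.p(1-p) -- an F_ST-like divergence per
branch.

All randomness derives from a single root seed; each operation draws from its
own child stream (``seed, stream-offset`` pairs) so that outputs are
bit-reproducible and adding one stage does not perturb another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

__all__ = [
    "SuperPop",
    "AdmixtureSpec",
    "SimConfig",
    "FrequencyPanel",
    "simulate_frequencies",
    "simulate_genotypes",
    "inject_ld_blocks",
    "assign_coordinates",
    "ascertain_aims",
    "studylike_config",
    "simulate_dataset",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# stream offsets for child RNGs (root seed spawns one stream per stage)
_STREAM_FREQ = 1
_STREAM_GENO = 2
_STREAM_LD = 3
_STREAM_COORD = 4
_STREAM_AIMS = 5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,)))


@dataclass
class SuperPop:
    """A super-population: branch drift from the root plus leaf populations.

    ``pops`` maps population label -> drift parameter of the branch from the
    super-population node down to that leaf.
    """

    drift: float
    pops: dict[str, float]


@dataclass
class AdmixtureSpec:
    """An admixed population drawing allele copies from source populations."""

    target: str
    sources: tuple[str, ...]
    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        props = np.asarray(self.proportions, dtype=float)
        if len(self.sources) != len(props):
            raise ConfigError("admixture sources and proportions differ in length")
        if (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ConfigError("mixing proportions must be nonnegative and sum to 1")


@dataclass
class SimConfig:
    """Configuration for one simulated dataset.

    Parameters
    ----------
    tree
        Super-population label -> :class:`SuperPop`.  Drift parameters are
        Balding-Nichols F values in (0, 1).
    n_per_pop
        Diploid individuals per population (including admixed targets).
    m_snps
        Number of biallelic sites.
    ancestral_maf_range
        Ancestral frequencies are drawn uniformly from this interval; the
        default floor of 0.05 keeps most sites polymorphic (monomorphic leaf
        columns can still arise through drift and are handled downstream).
    admixture_specs
        Admixed target populations (labels must not appear in the tree).
    ld_block
        Optional (block length in SNPs, copy-noise probability).
    coordinate_layout
        "uniform" or "clustered"; see :func:`assign_coordinates`.
    """

    tree: dict[str, SuperPop]
    n_per_pop: int = 30
    m_snps: int = 20_000
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    admixture_specs: list[AdmixtureSpec] = field(default_factory=list)
    ld_block: tuple[int, float] | None = None
    coordinate_layout: Literal["uniform", "clustered"] = "uniform"
    layout_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_snps < 1 or self.n_per_pop < 1:
            raise ConfigError("m_snps and n_per_pop must be >= 1")
        lo, hi = self.ancestral_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("ancestral_maf_range must lie within (0, 0.5]")
        for sp in self.tree.values():
            for f in (sp.drift, *sp.pops.values()):
                if not (0 < f < 1):
                    raise ConfigError(f"drift parameter {f} outside (0, 1)")
        leaf = set(self.leaf_populations())
        for spec in self.admixture_specs:
            if spec.target in leaf:
                raise ConfigError(f"admixed target {spec.target} is already a tree leaf")
            for s in spec.sources:
                if s not in leaf:
                    raise ConfigError(f"admixture source {s} not in tree")

    def leaf_populations(self) -> list[str]:
        return [p for sp in self.tree.values() for p in sp.pops]

    def all_populations(self) -> list[str]:
        return self.leaf_populations() + [a.target for a in self.admixture_specs]

    def super_of(self) -> dict[str, str]:
        """Population -> super-population label (admixed targets map to 'ADMIX')."""
        out = {p: s for s, sp in self.tree.items() for p in sp.pops}
        for a in self.admixture_specs:
            out[a.target] = "ADMIX"
        return out


@dataclass
class FrequencyPanel:
    """Ancestral and per-population alternate-allele frequencies."""

    ancestral_freq: np.ndarray          # (m,)
    pop_freq: pd.DataFrame              # populations x sites

    def __post_init__(self) -> None:
        vals = self.pop_freq.to_numpy()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("population frequencies must lie in [0, 1]")


def _bn_draw(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Balding-Nichols child frequencies: Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    scale = (1.0 - f) / f
    a = np.clip(p * scale, 1e-12, None)
    b = np.clip((1.0 - p) * scale, 1e-12, None)
    return rng.beta(a, b)


def simulate_frequencies(config: SimConfig) -> FrequencyPanel:
    """Draw ancestral and leaf-population allele frequencies down the tree."""
    rng = _rng(config.seed, _STREAM_FREQ)
    lo, hi = config.ancestral_maf_range
    anc = rng.uniform(lo, hi, size=config.m_snps)
    rows: dict[str, np.ndarray] = {}
    for sp in config.tree.values():
        p_super = _bn_draw(rng, anc, sp.drift)
        for pop, f in sp.pops.items():
            rows[pop] = _bn_draw(rng, p_super, f)
    pop_freq = pd.DataFrame.from_dict(rows, orient="index")
    return FrequencyPanel(ancestral_freq=anc, pop_freq=pop_freq)


def simulate_genotypes(panel: FrequencyPanel, config: SimConfig) -> GenotypeMatrix:
    """Draw diploid genotypes from population frequencies.

    Unadmixed individuals: genotype ~ Binomial(2, p_pop).  Admixed
    individuals: each of the two allele copies independently chooses a source
    population with its mixing proportion, then is a Bernoulli(p_source) draw.
    """
    rng = _rng(config.seed, _STREAM_GENO)
    n = config.n_per_pop
    m = config.m_snps
    blocks: list[np.ndarray] = []
    samples: list[str] = []
    populations: list[str] = []

    for pop in config.leaf_populations():
        p = panel.pop_freq.loc[pop].to_numpy()
        g = rng.binomial(2, p[None, :], size=(n, m)).astype(np.int8)
        blocks.append(g)
        samples.extend(f"{pop}_{i:03d}" for i in range(n))
        populations.extend([pop] * n)

    for spec in config.admixture_specs:
        src_freq = np.stack([panel.pop_freq.loc[s].to_numpy() for s in spec.sources])
        props = np.asarray(spec.proportions)
        g = np.zeros((n, m), dtype=np.int8)
        for _copy in range(2):
            src_choice = rng.choice(len(spec.sources), size=(n, m), p=props)
            p_copy = src_freq[src_choice, np.arange(m)[None, :]]
            g += (rng.random((n, m)) < p_copy).astype(np.int8)
        blocks.append(g)
        samples.extend(f"{spec.target}_{i:03d}" for i in range(n))
        populations.extend([spec.target] * n)

    dosages = np.vstack(blocks)
    sites = pd.DataFrame({
        "chrom": "1",
        "pos": np.arange(1, m + 1, dtype=np.int64),
        "ref": "A",
        "alt": "G",
        "id": [f"snp{j}" for j in range(m)],
    })
    return GenotypeMatrix(dosages=dosages, sites=sites,
                          samples=samples, populations=populations)


def empirical_pop_freq(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-population alt-allele frequency estimated from the dosage matrix."""
    rows = {}
    miss = g.missing_mask()
    d = np.where(miss, 0, g.dosages).astype(float)
    for pop, idx in g.pop_indices().items():
        n_alleles = 2.0 * (~miss[idx]).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rows[pop] = np.where(n_alleles > 0, d[idx].sum(axis=0) / n_alleles, 0.0)
    return pd.DataFrame.from_dict(rows, orient="index")


def inject_ld_blocks(
    g: GenotypeMatrix,
    block_len: int,
    noise: float,
    seed: int,
    pop_freq: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Copy-with-noise LD blocks over consecutive sites.

    Within each run of ``block_len`` consecutive sites, sites 2..block_len
    become copies of the first site's genotype column; each copied entry is
    then, with probability ``noise``, resampled as Binomial(2, p) from that
    site's own population frequency.  ``noise=1`` therefore reproduces the
    original genotype distribution; ``noise=0`` gives perfect within-block LD.

    ``pop_freq`` defaults to the empirical per-population frequencies of the
    input matrix (so admixed populations are covered too).
    """
    if block_len < 1:
        raise ConfigError("block_len must be >= 1")
    if not (0 <= noise <= 1):
        raise ConfigError("noise must lie in [0, 1]")
    if block_len == 1:
        return g
    rng = _rng(seed, _STREAM_LD)
    if pop_freq is None:
        pop_freq = empirical_pop_freq(g)
    d = g.dosages.copy()
    pop_idx = g.pop_indices()
    m = g.n_sites
    for start in range(0, m, block_len):
        stop = min(start + block_len, m)
        anchor = d[:, start].copy()
        for j in range(start + 1, stop):
            col = anchor.copy()
            resample = rng.random(g.n_samples) < noise
            if resample.any():
                for pop, idx in pop_idx.items():
                    sel = idx[resample[idx]]
                    if sel.size:
                        p = float(pop_freq.loc[pop].iloc[j])
                        col[sel] = rng.binomial(2, p, size=sel.size).astype(np.int8)
            d[:, j] = col
    return GenotypeMatrix(dosages=d, sites=g.sites.copy(),
                          samples=list(g.samples), populations=list(g.populations))


def assign_coordinates(
    g: GenotypeMatrix,
    layout: Literal["uniform", "clustered"],
    *,
    n_chrom: int = 1,
    chrom_length: int = 100_000_000,
    cluster_span: int = 10_000,
    gap: int = 500_000,
    snps_per_cluster: int = 20,
    seed: int = 0,
) -> GenotypeMatrix:
    """Assign physical coordinates to the sites.

    uniform
        Sites split evenly across ``n_chrom`` chromosomes and evenly spaced
        along each (dispersed, genome-like layout).
    clustered
        Sites packed into gene-like clusters of ``snps_per_cluster`` sites
        spanning ``cluster_span`` bp, separated by ``gap`` bp (exome-like
        layout).

    Positions are strictly increasing within each chromosome.
    """
    if layout not in ("uniform", "clustered"):
        raise ConfigError(f"unknown coordinate layout {layout!r}")
    if layout == "clustered" and cluster_span < snps_per_cluster:
        raise ConfigError("cluster span shorter than 1 bp per SNP")
    m = g.n_sites
    per_chrom = int(np.ceil(m / n_chrom))
    chroms: list[str] = []
    positions: list[int] = []
    for c in range(n_chrom):
        count = min(per_chrom, m - c * per_chrom)
        if count <= 0:
            break
        name = str(c + 1)
        if layout == "uniform":
            spacing = max(chrom_length // (count + 1), 1)
            pos = (np.arange(count, dtype=np.int64) + 1) * spacing
        else:
            within = np.linspace(0, cluster_span - 1, num=min(snps_per_cluster, count),
                                 dtype=np.int64)
            pos_list: list[int] = []
            k = 0
            cluster = 0
            while k < count:
                take = min(snps_per_cluster, count - k)
                base = cluster * (cluster_span + gap) + 1
                offs = np.linspace(0, cluster_span - 1, num=take, dtype=np.int64)
                offs = np.unique(offs)
                while len(offs) < take:  # degenerate tiny spans
                    offs = np.arange(take, dtype=np.int64)
                pos_list.extend((base + offs).tolist())
                k += take
                cluster += 1
            pos = np.asarray(pos_list[:count], dtype=np.int64)
        chroms.extend([name] * count)
        positions.extend(pos.tolist())
    sites = g.sites.copy()
    sites["chrom"] = chroms
    sites["pos"] = np.asarray(positions, dtype=np.int64)
    return GenotypeMatrix(dosages=g.dosages.copy(), sites=sites,
                          samples=list(g.samples), populations=list(g.populations))


def maf_variance_of_panel(pop_freq: pd.DataFrame) -> np.ndarray:
    """Across-population variance of the pooled-minor-allele frequency.

    The minor allele is chosen on the pooled (unweighted mean) frequency, so
    the per-site number is a variance of the same allele's frequency in every
    population.  Sample variance (n_pops - 1 denominator).
    """
    f = pop_freq.to_numpy()
    pooled = f.mean(axis=0)
    flip = pooled > 0.5
    f = np.where(flip[None, :], 1.0 - f, f)
    return f.var(axis=0, ddof=1)


def ascertain_aims(
    panel: FrequencyPanel,
    mode: Literal["maf_variance_top", "delta_pair"],
    fraction_aims: float,
    n_sites: int,
    seed: int = 0,
    pair: tuple[str, str] | None = None,
) -> np.ndarray:
    """Select a site panel enriched for ancestry-informative markers.

    A ``fraction_aims`` share of the ``n_sites`` selected ids is drawn from
    the top decile of the informativeness ranking (across-population MAF
    variance, or |delta p| for a named population pair); the remainder is a
    uniform draw from the leftover sites.  No duplicates.
    """
    if not (0 <= fraction_aims <= 1):
        raise ConfigError("fraction_aims must lie in [0, 1]")
    m = len(panel.ancestral_freq)
    if n_sites > m:
        raise ValueError(f"n_sites={n_sites} exceeds available sites ({m})")
    rng = _rng(seed, _STREAM_AIMS)
    if mode == "maf_variance_top":
        score = maf_variance_of_panel(panel.pop_freq)
    elif mode == "delta_pair":
        if pair is None:
            raise ConfigError("delta_pair mode needs a population pair")
        a, b = pair
        score = np.abs(panel.pop_freq.loc[a].to_numpy() - panel.pop_freq.loc[b].to_numpy())
    else:
        raise ConfigError(f"unknown ascertainment mode {mode!r}")

    n_aims = int(round(fraction_aims * n_sites))
    order = np.argsort(score, kind="stable")[::-1]
    top_decile = order[: max(m // 10, n_aims)]
    chosen_aims = rng.choice(top_decile, size=n_aims, replace=False) if n_aims else \
        np.empty(0, dtype=np.intp)
    rest_pool = np.setdiff1d(np.arange(m), chosen_aims, assume_unique=False)
    chosen_rest = rng.choice(rest_pool, size=n_sites - n_aims, replace=False)
    out = np.sort(np.concatenate([chosen_aims, chosen_rest]).astype(np.intp))
    return out


# ---------------------------------------------------------------------------
# Canonical study-like configuration
# ---------------------------------------------------------------------------

def studylike_config(
    seed: int = 0,
    n_super: int = 5,
    pops_per_super: int = 3,
    n_per_pop: int = 30,
    m_snps: int = 20_000,
    drift_super: float = 0.08,
    drift_pop: float = 0.01,
) -> SimConfig:
    """Default study-like configuration: 5 super-populations x 3 populations,
    30 individuals per population, 20,000 SNPs, branch drift 0.08 between and
    0.01 within super-populations, plus one 70/30 admixed population."""
    tree = {
        f"SP{s}": SuperPop(
            drift=drift_super,
            pops={f"SP{s}P{p}": drift_pop for p in range(1, pops_per_super + 1)},
        )
        for s in range(1, n_super + 1)
    }
    specs = [AdmixtureSpec(target="ADM1", sources=("SP1P1", "SP2P1"),
                           proportions=(0.7, 0.3))]
    return SimConfig(tree=tree, n_per_pop=n_per_pop, m_snps=m_snps,
                     admixture_specs=specs, seed=seed)


def simulate_dataset(config: SimConfig) -> tuple[FrequencyPanel, GenotypeMatrix]:
    """Frequencies + genotypes + coordinates + optional LD blocks in one call."""
    panel = simulate_frequencies(config)
    g = simulate_genotypes(panel, config)
    g = assign_coordinates(g, config.coordinate_layout,
                           seed=config.seed, **config.layout_params)
    if config.ld_block is not None:
        block_len, noise = config.ld_block
        g = inject_ld_blocks(g, block_len, noise, seed=config.seed)
    return panel, g
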