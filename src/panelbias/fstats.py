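"""Allele frequencies, Hudson F_ST, f3/f4 statistics and the block jackknife.

Estimators
----------
Hudson F_ST (ratio of averages): per usable site

    N_j = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    D_j = p1(1-p2) + p2(1-p1)

with p the population alternate-allele frequency and n the observed allele
count (2 x non-missing individuals); the estimate is sum(N)/sum(D).  Negative
estimates are reported as computed (no clamping).

f3(C; A, B): per-site (c-a)(c-b) - c(1-c)/(n_C - 1) (the second term removes
the sampling-noise bias of C's squared frequency); significantly negative
values indicate C is admixed between sources related to A and B.

f4(A, B; C, D): per-site (a-b)(c-d), no bias correction needed; nonzero
values indicate gene flow violating the tree ((A,B),(C,D)).

Standard errors come from a weighted delete-one-block jackknife over
contiguous genomic blocks (robust to local LD), yielding the Z scores used
for significance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

__all__ = [
    "AlleleFrequencyTable",
    "FStatResult",
    "allele_frequencies",
    "coordinate_blocks",
    "block_jackknife",
    "hudson_fst_pair",
    "fst_matrix",
    "f3",
    "f4",
    "f3_scan",
]


@dataclass
class AlleleFrequencyTable:
    """Per-population alternate-allele frequencies and observed allele counts.

    ``freq`` and ``count`` are populations x sites DataFrames; ``count`` holds
    observed allele counts (2 x non-missing individuals).  Frequencies where
    the count is below 2 are unusable and set to NaN.  ``sites`` carries the
    coordinates for block construction.
    """

    freq: pd.DataFrame
    count: pd.DataFrame
    sites: pd.DataFrame

    @property
    def populations(self) -> list[str]:
        return list(self.freq.index)

    def pair_mask(self, pops: list[str]) -> np.ndarray:
        """Sites usable for a statistic over ``pops``: count >= 2 in each."""
        m = np.ones(self.freq.shape[1], dtype=bool)
        for p in pops:
            m &= self.count.loc[p].to_numpy() >= 2
        return m


def allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencyTable:
    """Estimate per-population alt-allele frequencies from dosages."""
    pop_idx = g.pop_indices()
    if any(idx.size == 0 for idx in pop_idx.values()):
        raise ValueError("population with zero samples")
    miss = g.missing_mask()
    d = np.where(miss, 0, g.dosages).astype(float)
    freq_rows, count_rows = {}, {}
    for pop, idx in pop_idx.items():
        n = 2.0 * (~miss[idx]).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, d[idx].sum(axis=0) / np.where(n > 0, n, 1), np.nan)
        p = np.where(n >= 2, p, np.nan)
        freq_rows[pop] = p
        count_rows[pop] = n
    return AlleleFrequencyTable(
        freq=pd.DataFrame.from_dict(freq_rows, orient="index"),
        count=pd.DataFrame.from_dict(count_rows, orient="index"),
        sites=g.sites.copy(),
    )


# ---------------------------------------------------------------------------
# Blocks and jackknife
# ---------------------------------------------------------------------------

def coordinate_blocks(sites: pd.DataFrame, block_mb: float = 5.0,
                      n_fallback_blocks: int = 100) -> np.ndarray:
    """Assign each site to a contiguous jackknife block.

    Default: 5 Mb coordinate blocks per chromosome.  If coordinates are
    absent (or collapse into a single block), fall back to
    ``n_fallback_blocks`` equal-count contiguous blocks.
    """
    m = len(sites)
    if m == 0:
        return np.empty(0, dtype=np.intp)
    if "pos" in sites.columns and "chrom" in sites.columns:
        chrom = sites["chrom"].to_numpy()
        pos = sites["pos"].to_numpy()
        block_bp = int(block_mb * 1_000_000)
        labels = np.empty(m, dtype=np.intp)
        next_id = 0
        for c in pd.unique(chrom):
            sel = chrom == c
            b = (pos[sel] - pos[sel].min()) // block_bp
            uniq, inv = np.unique(b, return_inverse=True)
            labels[sel] = inv + next_id
            next_id += len(uniq)
        if next_id >= 2:
            return labels
    # fallback: equal-count contiguous blocks
    k = min(n_fallback_blocks, m)
    return (np.arange(m) * k // m).astype(np.intp)


def block_jackknife(
    values: np.ndarray,
    weights: np.ndarray,
    blocks: np.ndarray,
) -> tuple[float, float]:
    """Weighted delete-one-block jackknife of a weighted mean.

    ``values`` are per-site statistics, ``weights`` per-site weights,
    ``blocks`` integer block labels.  Returns (overall weighted mean,
    jackknife SE) using the unequal-block-size jackknife variance

        var = (1/g) * sum_j [ (h_j T - (h_j - 1) T_{-j} - T_J)^2 / (h_j - 1) ]

    with h_j = W / w_j (total over block weight) and T_J the bias-corrected
    jackknife estimate.  Degenerate identical leave-one-out estimates give
    SE = 0.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    blocks = np.asarray(blocks)
    uniq = np.unique(blocks)
    if len(uniq) < 2:
        raise ValueError("block jackknife needs >= 2 non-empty blocks")
    W = weights.sum()
    if W <= 0:
        raise ValueError("total weight must be positive")
    total = float(np.sum(values * weights))
    theta = total / W

    w_j = np.array([weights[blocks == b].sum() for b in uniq])
    t_j = np.array([values[blocks == b] @ weights[blocks == b] for b in uniq])
    if np.any(w_j >= W):
        raise ValueError("a single block carries all the weight")
    theta_del = (total - t_j) / (W - w_j)      # leave-one-block-out estimates
    g_blocks = len(uniq)
    h = W / w_j
    theta_jack = g_blocks * theta - np.sum((1.0 - w_j / W) * theta_del)
    pseudo = h * theta - (h - 1.0) * theta_del - theta_jack
    var = np.sum(pseudo**2 / (h - 1.0)) / g_blocks
    se = float(np.sqrt(max(var, 0.0)))
    return theta, se


def _zscore(est: float, se: float) -> float:
    if se > 0:
        return est / se
    return float("inf") if est >= 0 else float("-inf")


@dataclass
class FStatResult:
    """An f-statistic (or F_ST) estimate with jackknife uncertainty."""

    statistic: str
    labels: tuple[str, ...]
    estimate: float
    jackknife_se: float
    z_score: float
    n_blocks: int
    n_snps_used: int


# ---------------------------------------------------------------------------
# Hudson F_ST
# ---------------------------------------------------------------------------

def _hudson_terms(freqs: AlleleFrequencyTable, pop_a: str, pop_b: str
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p1 = freqs.freq.loc[pop_a].to_numpy()
    p2 = freqs.freq.loc[pop_b].to_numpy()
    n1 = freqs.count.loc[pop_a].to_numpy()
    n2 = freqs.count.loc[pop_b].to_numpy()
    usable = freqs.pair_mask([pop_a, pop_b])
    # exclude sites monomorphic across the pair (D_j = 0 contributes nothing)
    with np.errstate(invalid="ignore"):
        d = p1 * (1 - p2) + p2 * (1 - p1)
    usable &= np.nan_to_num(d) > 0
    idx = np.flatnonzero(usable)
    p1, p2, n1, n2 = p1[idx], p2[idx], n1[idx], n2[idx]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den, idx


def hudson_fst_pair(
    freqs: AlleleFrequencyTable,
    pop_a: str,
    pop_b: str,
    blocks: np.ndarray | None = None,
) -> FStatResult:
    """Hudson F_ST between two populations (ratio of averages), with a block
    jackknife on the ratio when blocks are available."""
    num, den, idx = _hudson_terms(freqs, pop_a, pop_b)
    if len(idx) == 0:
        raise ValueError(f"no usable sites for F_ST({pop_a}, {pop_b})")
    est = float(num.sum() / den.sum())
    if blocks is None:
        blocks = coordinate_blocks(freqs.sites)
    b = blocks[idx]
    uniq = np.unique(b)
    if len(uniq) >= 2:
        # delete-one-block jackknife of the ratio of sums
        tot_n, tot_d = num.sum(), den.sum()
        n_j = np.array([num[b == u].sum() for u in uniq])
        d_j = np.array([den[b == u].sum() for u in uniq])
        theta_del = (tot_n - n_j) / (tot_d - d_j)
        g_blocks = len(uniq)
        h = tot_d / d_j
        theta_jack = g_blocks * est - np.sum((1.0 - d_j / tot_d) * theta_del)
        pseudo = h * est - (h - 1.0) * theta_del - theta_jack
        var = np.sum(pseudo**2 / (h - 1.0)) / g_blocks
        se = float(np.sqrt(max(var, 0.0)))
    else:
        se = 0.0
    return FStatResult("fst", (pop_a, pop_b), est, se, _zscore(est, se),
                       int(len(uniq)), int(len(idx)))


def fst_matrix(
    freqs: AlleleFrequencyTable,
    populations: list[str] | None = None,
    blocks: np.ndarray | None = None,
) -> pd.DataFrame:
    """Symmetric pairwise Hudson F_ST matrix (diagonal exactly 0)."""
    pops = populations if populations is not None else freqs.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for a, b in combinations(pops, 2):
        est = hudson_fst_pair(freqs, a, b, blocks=blocks).estimate
        mat.loc[a, b] = mat.loc[b, a] = est
    return mat


# ---------------------------------------------------------------------------
# f3 / f4
# ---------------------------------------------------------------------------

def f3(
    freqs: AlleleFrequencyTable,
    target: str,
    source_a: str,
    source_b: str,
    blocks: np.ndarray | None = None,
) -> FStatResult:
    """f3(target; source_a, source_b) with jackknife SE and Z score."""
    c = freqs.freq.loc[target].to_numpy()
    a = freqs.freq.loc[source_a].to_numpy()
    b = freqs.freq.loc[source_b].to_numpy()
    nc = freqs.count.loc[target].to_numpy()
    usable = freqs.pair_mask([target, source_a, source_b])
    idx = np.flatnonzero(usable)
    if len(idx) == 0:
        raise ValueError("no usable sites for f3")
    c, a, b, nc = c[idx], a[idx], b[idx], nc[idx]
    t = (c - a) * (c - b) - c * (1 - c) / (nc - 1)
    if blocks is None:
        blocks = coordinate_blocks(freqs.sites)
    est, se = block_jackknife(t, np.ones_like(t), blocks[idx])
    return FStatResult("f3", (target, source_a, source_b), est, se,
                       _zscore(est, se), int(len(np.unique(blocks[idx]))),
                       int(len(idx)))


def f4(
    freqs: AlleleFrequencyTable,
    pop_a: str,
    pop_b: str,
    pop_c: str,
    pop_d: str,
    blocks: np.ndarray | None = None,
) -> FStatResult:
    """f4(pop_a, pop_b; pop_c, pop_d) with jackknife SE and Z score."""
    pops = [pop_a, pop_b, pop_c, pop_d]
    if len(set(pops)) != 4:
        raise ValueError("f4 needs four distinct populations")
    a, b, c, d = (freqs.freq.loc[p].to_numpy() for p in pops)
    idx = np.flatnonzero(freqs.pair_mask(pops))
    if len(idx) == 0:
        raise ValueError("no usable sites for f4")
    t = (a[idx] - b[idx]) * (c[idx] - d[idx])
    if blocks is None:
        blocks = coordinate_blocks(freqs.sites)
    est, se = block_jackknife(t, np.ones_like(t), blocks[idx])
    return FStatResult("f4", tuple(pops), est, se, _zscore(est, se),
                       int(len(np.unique(blocks[idx]))), int(len(idx)))


def f3_scan(
    freqs: AlleleFrequencyTable,
    populations: list[str] | None = None,
    blocks: np.ndarray | None = None,
) -> pd.DataFrame:
    """f3 for every triad (C; A, B), A/B unordered, one row per triad."""
    pops = populations if populations is not None else freqs.populations
    rows = []
    for target in pops:
        others = [p for p in pops if p != target]
        for a, b in combinations(others, 2):
            r = f3(freqs, target, a, b, blocks=blocks)
            rows.append({
                "target": target, "source_a": a, "source_b": b,
                "f3": r.estimate, "se": r.jackknife_se, "z": r.z_score,
                "n_snps": r.n_snps_used, "n_blocks": r.n_blocks,
            })
    return pd.DataFrame(rows)
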