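"""Windowed greedy pairwise LD pruning.

The criterion is the standard genotype-correlation one: squared Pearson
correlation of alt-allele dosages (composite LD — no phasing involved).
Windows are defined in physical distance (kb) from the window's first SNP,
the step between windows in SNP count, mirroring the mixed-unit convention
of the widely used ``--indep-pairwise`` protocol.

Within a window the highest-r² pair above the threshold is resolved first;
the member with the lower minor-allele frequency is pruned (ties: the
later-positioned SNP), which keeps the more informative marker and makes the
procedure deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["PruneResult", "genotype_r2", "indep_pairwise", "pruning_summary"]


@dataclass
class PruneResult:
    kept: np.ndarray      # site indices into the input matrix, ascending
    pruned: np.ndarray
    window_kb: float
    step_snps: int
    r2_thresh: float

    @property
    def fraction_pruned(self) -> float:
        total = len(self.kept) + len(self.pruned)
        return len(self.pruned) / total if total else 0.0


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise non-missing entries; returns 0 when either vector
    is constant, and 0 (with a warning) when fewer than two complete pairs
    exist.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        warnings.warn("genotype_r2: fewer than 2 complete pairs; returning 0",
                      stacklevel=2)
        return 0.0
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def _maf(col: np.ndarray) -> float:
    ok = col != MISSING
    if ok.sum() == 0:
        return 0.0
    p = col[ok].astype(float).mean() / 2.0
    return min(p, 1.0 - p)


def _pairwise_r2(d: np.ndarray) -> np.ndarray:
    """All-pairs r² of dosage columns (missing entries mean-imputed here is
    wrong for the contract, so columns with missingness fall back to the
    pairwise-complete scalar path)."""
    m = d.shape[1]
    if (d == MISSING).any():
        out = np.zeros((m, m))
        for a in range(m):
            for b in range(a + 1, m):
                out[a, b] = out[b, a] = genotype_r2(d[:, a], d[:, b])
        return out
    x = d.astype(float)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    xn = x / sd_safe
    r = (xn.T @ xn) / x.shape[0]
    r[sd == 0, :] = 0.0
    r[:, sd == 0] = 0.0
    np.fill_diagonal(r, 0.0)
    return r * r


def indep_pairwise(
    g: GenotypeMatrix,
    window_kb: float = 10_000,
    step_snps: int = 10,
    r2_thresh: float = 0.1,
) -> PruneResult:
    """Greedy sliding-window LD pruning over coordinate-sorted SNPs.

    Per chromosome: the window is the maximal run of not-yet-pruned SNPs
    whose positions lie within ``window_kb`` kilobases of the window's first
    SNP.  Within the window, pairs exceeding ``r2_thresh`` are resolved
    highest-r² first by pruning the lower-MAF member; the window start then
    advances ``step_snps`` surviving SNPs.  A SNP pruned in any window stays
    pruned.  Monomorphic sites are removed beforehand with a logged count.
    """
    chrom = g.sites["chrom"].to_numpy()
    pos = g.sites["pos"].to_numpy()
    for c in pd.unique(chrom):
        p = pos[chrom == c]
        if np.any(np.diff(p) <= 0):
            raise ValueError(f"sites not coordinate-sorted on chromosome {c}")

    d_all = g.dosages
    mono = np.array([_maf(d_all[:, j]) == 0.0 for j in range(g.n_sites)])
    if mono.any():
        logger.info("indep_pairwise: dropped %d monomorphic sites", int(mono.sum()))
    usable = np.flatnonzero(~mono)

    window_bp = int(window_kb * 1000)
    pruned_global: list[int] = []
    kept_global: list[int] = []

    for c in pd.unique(chrom):
        idx = usable[chrom[usable] == c]
        if idx.size == 0:
            continue
        alive = list(idx)            # in coordinate order
        mafs = {j: _maf(d_all[:, j]) for j in idx}
        start_ptr = 0
        while start_ptr < len(alive):
            w0 = alive[start_ptr]
            # maximal run of surviving SNPs within window_bp of the first
            end_ptr = start_ptr
            while (end_ptr + 1 < len(alive)
                   and pos[alive[end_ptr + 1]] - pos[w0] <= window_bp):
                end_ptr += 1
            window = alive[start_ptr:end_ptr + 1]
            if len(window) > 1:
                sub = d_all[:, window]
                r2 = _pairwise_r2(sub)
                local_alive = np.ones(len(window), dtype=bool)
                while True:
                    masked = np.where(
                        local_alive[:, None] & local_alive[None, :], r2, 0.0
                    )
                    np.fill_diagonal(masked, 0.0)
                    a, b = np.unravel_index(np.argmax(masked), masked.shape)
                    if masked[a, b] <= r2_thresh:
                        break
                    ja, jb = window[min(a, b)], window[max(a, b)]
                    # prune the lower-MAF member; tie -> the later-positioned
                    victim = ja if mafs[ja] < mafs[jb] else jb
                    local_alive[window.index(victim)] = False
                    pruned_global.append(victim)
                removed = {window[k] for k in range(len(window)) if not local_alive[k]}
                if removed:
                    alive = [j for j in alive if j not in removed]
            start_ptr += step_snps
        kept_global.extend(alive)

    kept = np.sort(np.asarray(kept_global, dtype=np.intp))
    pruned = np.sort(np.concatenate([
        np.asarray(pruned_global, dtype=np.intp),
        np.flatnonzero(mono).astype(np.intp),
    ]))
    return PruneResult(kept=kept, pruned=pruned, window_kb=window_kb,
                       step_snps=step_snps, r2_thresh=r2_thresh)


def pruning_summary(n_before: int, n_after: int) -> float:
    """Fraction of markers removed by pruning."""
    if n_before <= 0:
        raise ValueError("empty input set")
    if n_after > n_before:
        raise ValueError("after-count exceeds before-count")
    return (n_before - n_after) / n_before
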