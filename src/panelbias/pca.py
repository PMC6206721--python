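"""Principal components analysis of genotypes with the population-genetics
normalization (centering and binomial scaling per site) and iterative
sigma-threshold outlier removal.

Each site column is mean-imputed at missing entries, centered by its mean mu
and scaled by sqrt(p(1-p)) with p = mu/2 — the variance a binomially sampled
allele frequency would have, so drifted (ancestry-informative) sites are not
drowned out by common-variant variance.  The decomposition is of the
sample x sample covariance of the normalized matrix divided by the site
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["PCAResult", "normalize_genotypes", "run_pca", "remove_outliers"]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray          # descending
    eigenvectors: np.ndarray         # samples x components, unit columns
    samples: list[str]
    populations: list[str]
    n_sites_used: int
    removed_outliers: list[list[str]] = field(default_factory=list)


def normalize_genotypes(g: GenotypeMatrix, pseudocount: bool = False) -> np.ndarray:
    """Impute, center and binomially scale the dosage matrix.

    Missing entries are imputed with the site mean; each column is centered
    and divided by sqrt(p(1-p)), p = mean/2 (optionally with the +1/+2
    pseudo-count variant).  Monomorphic columns are dropped with a logged
    count.
    """
    if g.n_samples < 2:
        raise ValueError("PCA normalization needs >= 2 samples")
    d = g.dosages.astype(float)
    miss = g.missing_mask()
    n_obs = (~miss).sum(axis=0).astype(float)
    col_sum = np.where(miss, 0.0, d).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(n_obs > 0, col_sum / np.where(n_obs > 0, n_obs, 1), 0.0)
    d = np.where(miss, mu[None, :], d)
    if pseudocount:
        p = (col_sum + 1.0) / (2.0 * n_obs + 2.0)
    else:
        p = mu / 2.0
    var = p * (1.0 - p)
    # constant columns (e.g. all-heterozygote) carry no variation even when
    # p(1-p) > 0; they are dropped together with the p(1-p) = 0 ones
    empirical_sd = d.std(axis=0)
    keep = (var > 0) & (empirical_sd > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("normalize_genotypes: dropped %d monomorphic sites", n_dropped)
    if not keep.any():
        raise ValueError("all sites monomorphic; nothing to analyze")
    x = (d[:, keep] - mu[keep][None, :]) / np.sqrt(var[keep])[None, :]
    return x


def run_pca(g: GenotypeMatrix, n_components: int = 10,
            pseudocount: bool = False) -> PCAResult:
    """Eigendecomposition of the normalized sample covariance.

    Returns eigenvalues in descending order and unit-norm eigenvectors with
    the sign convention that each vector's largest-magnitude entry is
    positive.
    """
    x = normalize_genotypes(g, pseudocount=pseudocount)
    n, m = x.shape
    n_components = min(n_components, n - 1, m)
    if n_components < 1:
        raise ValueError("n_components must be >= 1 after clipping")
    cov = (x @ x.T) / m
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order][:n_components]
    evecs = evecs[:, order][:, :n_components]
    # sign convention: largest-|entry| positive
    for k in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    return PCAResult(eigenvalues=evals, eigenvectors=evecs,
                     samples=list(g.samples), populations=list(g.populations),
                     n_sites_used=m)


def remove_outliers(
    g: GenotypeMatrix,
    sigma: float = 6.0,
    topk: int = 10,
    max_iter: int = 5,
    n_components: int = 10,
) -> PCAResult:
    """Iterative PCA outlier removal.

    Each iteration runs PCA and removes samples whose score on any of the
    top-``topk`` components deviates from that component's mean by more than
    ``sigma`` standard deviations; stops when an iteration removes nobody or
    after ``max_iter`` iterations.  The returned result carries the removal
    history (one list of sample ids per iteration that removed samples).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    current = g
    history: list[list[str]] = []
    result = None
    for _ in range(max_iter):
        result = run_pca(current, n_components=max(n_components, topk))
        scores = result.eigenvectors[:, :topk]
        mean = scores.mean(axis=0)
        sd = scores.std(axis=0, ddof=1)
        sd = np.where(sd == 0, np.inf, sd)
        dev = np.abs(scores - mean) / sd
        outlier = (dev > sigma).any(axis=1)
        if not outlier.any():
            break
        removed = [current.samples[i] for i in np.flatnonzero(outlier)]
        history.append(removed)
        keep = np.flatnonzero(~outlier)
        if keep.size == 0:
            raise ValueError("outlier removal eliminated every sample")
        current = current.take_samples(keep)
    else:
        result = run_pca(current, n_components=max(n_components, topk))
    assert result is not None
    result.removed_outliers = history
    return result
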