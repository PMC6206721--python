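"""Maximum-likelihood admixture model (Q/F) via EM, with masked-entry
cross-validation over a range of K.

Model: individual i's two allele copies at site j are independent draws;
each copy chooses ancestry component k with probability q_ik and is then the
alternate allele with probability f_kj.  The log-likelihood over observed
genotypes g_ij in {0,1,2} is

    l(Q, F) = sum_ij [ g_ij log(sum_k q_ik f_kj)
                       + (2 - g_ij) log(sum_k q_ik (1 - f_kj)) ].

The EM updates (FRAPPE-style) ascend this likelihood monotonically; we run
plain EM from seeded random initialization — at the problem sizes this
package targets the quasi-Newton acceleration of the reference tools is
unnecessary.

Model choice uses masked-entry cross-validation: genotype cells are
partitioned into folds, each fold is masked in turn, the model is refit, and
the fold error is the mean squared difference between the observed dosage
and its prediction 2 * (Q F).  Absolute CV errors are panel-dependent, so
curves are also reported relative to the worst-fitting K in the range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GenotypeMatrix

__all__ = ["AdmixtureFit", "CVCurve", "admixture_fit", "cross_validation",
           "best_model", "match_components", "partition_cells"]

_EPS = 1e-6


@dataclass
class AdmixtureFit:
    Q: np.ndarray                # samples x K, rows sum to 1
    F: np.ndarray                # K x sites, clamped to [eps, 1-eps]
    loglik: float
    K: int
    n_iter: int
    converged: bool
    seed: int
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class CVCurve:
    k_values: list[int]
    mean_errors: list[float]
    fold_errors: dict[int, list[float]]
    boundary_minimum: bool = False

    @property
    def best_k(self) -> int:
        return best_model(self)

    def relative_errors(self) -> list[float]:
        """Errors relative to the worst-fitting (highest-error) K."""
        ref = max(self.mean_errors)
        return [e / ref for e in self.mean_errors]


def _loglik(g: np.ndarray, obs: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    p = np.clip(Q @ F, _EPS, 1 - _EPS)
    ll = np.where(obs, g * np.log(p) + (2 - g) * np.log1p(-p), 0.0)
    return float(ll.sum())


def admixture_fit(
    g: GenotypeMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 2000,
) -> AdmixtureFit:
    """Fit ancestry fractions Q and component frequencies F for one K by EM.

    Initialization: Q rows from a flat Dirichlet, F entries uniform on
    (0.05, 0.95), both seeded.  Missing genotypes are skipped in the
    likelihood and both update steps.  Iteration stops when the
    log-likelihood improves by less than ``tol`` or after ``max_iter``
    rounds; the per-iteration log-likelihood is non-decreasing.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > g.n_samples:
        raise ValueError("K exceeds the number of samples")
    dos = g.dosages.astype(float)
    obs = ~g.missing_mask()
    dos = np.where(obs, dos, 0.0)
    n, m = dos.shape
    rng = np.random.default_rng(seed)

    if K == 1:
        # closed form: F is the per-site mean dosage / 2
        n_obs = obs.sum(axis=0).astype(float)
        p = np.clip(dos.sum(axis=0) / np.maximum(2 * n_obs, 1), _EPS, 1 - _EPS)
        Q = np.ones((n, 1))
        F = p[None, :]
        ll = _loglik(dos, obs, Q, F)
        return AdmixtureFit(Q=Q, F=F, loglik=ll, K=1, n_iter=0, converged=True,
                            seed=seed, loglik_path=np.array([ll]))

    Q = rng.dirichlet(np.ones(K), size=n)
    F = rng.uniform(0.05, 0.95, size=(K, m))

    alt = dos                        # expected alt-copy counts per cell
    ref = np.where(obs, 2.0 - dos, 0.0)
    path = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        P = np.clip(Q @ F, _EPS, 1 - _EPS)          # n x m
        A = alt / P                                  # n x m
        B = ref / (1.0 - P)
        # E[alt copies from k at (i,j)] = Q_ik F_kj A_ij; sums reduce to
        # matrix products, no 3-D responsibility array needed
        num_f = F * (Q.T @ A)                        # K x m
        den_f = num_f + (1.0 - F) * (Q.T @ B)
        per_ik = Q * (A @ F.T) + Q * (B @ (1.0 - F).T)   # n x K
        F = np.clip(np.where(den_f > 0, num_f / np.where(den_f > 0, den_f, 1), F),
                    _EPS, 1 - _EPS)
        Q = per_ik / per_ik.sum(axis=1, keepdims=True)
        ll = _loglik(dos, obs, Q, F)
        path.append(ll)
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
    return AdmixtureFit(Q=Q, F=F, loglik=path[-1], K=K, n_iter=it,
                        converged=converged, seed=seed,
                        loglik_path=np.asarray(path))


def _fit_masked(dosages: np.ndarray, obs: np.ndarray, K: int, seed: int,
                tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    """EM on a raw dosage matrix with an explicit observation mask."""
    n, m = dosages.shape
    dos = np.where(obs, dosages, 0.0)
    rng = np.random.default_rng(seed)
    if K == 1:
        n_obs = np.maximum(obs.sum(axis=0), 1)
        p = np.clip(dos.sum(axis=0) / (2.0 * n_obs), _EPS, 1 - _EPS)
        Q = np.ones((n, 1))
        F = p[None, :]
        return Q, F, _loglik(dos, obs, Q, F)
    Q = rng.dirichlet(np.ones(K), size=n)
    F = rng.uniform(0.05, 0.95, size=(K, m))
    ref = np.where(obs, 2.0 - dos, 0.0)
    prev = -np.inf
    for _ in range(max_iter):
        P = np.clip(Q @ F, _EPS, 1 - _EPS)
        A = dos / P
        B = ref / (1.0 - P)
        num_f = F * (Q.T @ A)
        den_f = num_f + (1.0 - F) * (Q.T @ B)
        per_ik = Q * (A @ F.T) + Q * (B @ (1.0 - F).T)
        F = np.clip(np.where(den_f > 0, num_f / np.where(den_f > 0, den_f, 1), F),
                    _EPS, 1 - _EPS)
        Q = per_ik / per_ik.sum(axis=1, keepdims=True)
        ll = _loglik(dos, obs, Q, F)
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
    return Q, F, _loglik(dos, obs, Q, F)


def partition_cells(obs_mask: np.ndarray, folds: int, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Partition observed genotype cells into CV folds.

    Returns (cells, fold_of): the (row, col) indices of observed cells and an
    integer fold label per cell.  Every observed cell lands in exactly one
    fold.  Partitions that would leave a sample or site with no observed
    training entry in some fold are re-randomized (up to 10 attempts).
    """
    cells = np.argwhere(obs_mask)
    for _attempt in range(10):
        cand = rng.integers(0, folds, size=len(cells))
        ok = True
        for f in range(folds):
            masked = cells[cand == f]
            trial = obs_mask.copy()
            trial[masked[:, 0], masked[:, 1]] = False
            if (~trial.any(axis=1)).any() or (~trial.any(axis=0)).any():
                ok = False
                break
        if ok:
            return cells, cand
    raise ValueError("could not partition cells without emptying a row/column")


def cross_validation(
    g: GenotypeMatrix,
    k_range: range | list[int] = range(3, 11),
    folds: int = 5,
    restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-3,
    max_iter: int = 300,
) -> CVCurve:
    """Masked-entry cross-validation over K.

    Observed genotype cells are partitioned into ``folds`` random folds.  For
    each fold and K the fold is masked, the model refit ``restarts`` times
    from different seeds (best log-likelihood kept), and the fold error is
    the mean over masked cells of (g - 2 Q F)^2.  If a partition leaves a
    sample or site with no observed entries it is re-randomized (up to 10
    attempts).
    """
    if folds < 2:
        raise ValueError("need >= 2 folds")
    dosages = g.dosages.astype(float)
    obs_all = ~g.missing_mask()
    rng = np.random.default_rng(seed)
    cells, fold_of = partition_cells(obs_all, folds, rng)

    k_values = list(k_range)
    fold_errors: dict[int, list[float]] = {k: [] for k in k_values}
    for f in range(folds):
        masked = cells[fold_of == f]
        obs = obs_all.copy()
        obs[masked[:, 0], masked[:, 1]] = False
        truth = dosages[masked[:, 0], masked[:, 1]]
        for k in k_values:
            best = None
            for r in range(restarts):
                fit_seed = int(rng.integers(0, 2**31 - 1))
                Q, F, ll = _fit_masked(dosages, obs, k, fit_seed, tol, max_iter)
                if best is None or ll > best[2]:
                    best = (Q, F, ll)
            Q, F, _ = best
            pred = 2.0 * (Q @ F)[masked[:, 0], masked[:, 1]]
            fold_errors[k].append(float(np.mean((truth - pred) ** 2)))

    mean_errors = [float(np.mean(fold_errors[k])) for k in k_values]
    curve = CVCurve(k_values=k_values, mean_errors=mean_errors,
                    fold_errors=fold_errors)
    if int(np.argmin(mean_errors)) == len(k_values) - 1 and len(k_values) > 1:
        if all(mean_errors[i] >= mean_errors[i + 1] for i in range(len(k_values) - 1)):
            curve.boundary_minimum = True
            warnings.warn("CV error minimized at the boundary of the K range",
                          stacklevel=2)
    return curve


def best_model(curve: CVCurve) -> int:
    """K with the minimum mean CV error; ties resolved toward the smaller K."""
    if not curve.k_values:
        raise ValueError("empty CV curve")
    errs = np.asarray(curve.mean_errors)
    return int(curve.k_values[int(np.argmin(errs))])


def match_components(q_est: np.ndarray, q_true: np.ndarray) -> np.ndarray:
    """Best column permutation of ``q_est`` against ``q_true``.

    Components are label-free, so evaluation must search over relabelings;
    the best permutation minimizes the total variation distance between
    matched Q columns.  Returns the permuted estimate.
    """
    from itertools import permutations

    k = q_true.shape[1]
    if q_est.shape[1] != k:
        raise ValueError("component counts differ")
    best_perm, best_cost = None, np.inf
    for perm in permutations(range(k)):
        cost = 0.5 * np.abs(q_est[:, perm] - q_true).sum()
        if cost < best_cost:
            best_perm, best_cost = perm, cost
    return q_est[:, best_perm]
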