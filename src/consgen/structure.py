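"""Model-based ancestry estimation with EM and 10-fold cross-validation.

The likelihood is the standard admixture model: genotype g_il at a
biallelic locus is Binomial(2, f_il) with f_il = sum_k q_ik p_kl, Q the
row-stochastic ancestry matrix and P the ancestral allele frequencies.
The optimizer is a monotone EM (block ascent on Q and P); the number of
clusters K is selected by masking genotype entries in 10 folds and
scoring the held-out entries by binomial deviance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, ParameterError

logger = __import__("logging").getLogger("consgen")

EPS = 1e-6


@dataclass
class StructureResult:
    K: int
    Q: np.ndarray            # samples x K, rows sum to 1
    P: np.ndarray            # K x sites, in [EPS, 1-EPS]
    log_likelihood: float
    n_iter: int
    seed: int
    ll_path: np.ndarray = field(repr=False, default=None)


def _loglik(g: np.ndarray, mask: np.ndarray, Q: np.ndarray,
            P: np.ndarray) -> float:
    f = Q @ P
    f = np.clip(f, EPS, 1 - EPS)
    ll = np.where(mask, g * np.log(f) + (2 - g) * np.log(1 - f), 0.0)
    return float(ll.sum())


def _em_once(g, mask, K, rng, tol, max_iter):
    n, L = g.shape
    Q = rng.dirichlet(np.ones(K), size=n)
    P = np.clip(rng.random((K, L)), EPS, 1 - EPS)
    g0 = np.where(mask, g, 0.0)
    g2 = np.where(mask, 2.0 - g, 0.0)
    prev = -np.inf
    path = []
    for it in range(max_iter):
        f = np.clip(Q @ P, EPS, 1 - EPS)
        # responsibilities: derived and ancestral allele copies per k
        rd = g0 / f          # n x L
        ra = g2 / (1 - f)
        # joint M-step: both updates use responsibilities at the old (Q, P)
        alloc = (rd @ P.T + ra @ (1 - P).T) * Q      # n x K
        num_d = (Q.T @ rd) * P          # K x L
        num_a = (Q.T @ ra) * (1 - P)
        P = np.clip(num_d / np.maximum(num_d + num_a, 1e-300), EPS, 1 - EPS)
        denom = 2.0 * mask.sum(axis=1, keepdims=True)
        Q = alloc / np.maximum(denom, 1e-300)
        Q = Q / Q.sum(axis=1, keepdims=True)
        ll = _loglik(g, mask, Q, P)
        path.append(ll)
        if ll - prev < tol and it > 0:
            prev = ll
            break
        prev = ll
    return Q, P, prev, len(path), np.array(path)


def admixture_em(matrix: GenotypeMatrix, K: int, seed: int = 0,
                 tol: float = 1e-6, max_iter: int = 2000,
                 n_starts: int = 5) -> StructureResult:
    """Fit the K-cluster admixture model by EM; best of n_starts.

    Missing genotypes are skipped in all sums.  The per-iteration
    log-likelihood is non-decreasing (EM guarantee); K=1 reduces to
    observed allele frequencies.
    """
    if K < 1:
        raise ParameterError("K must be >= 1")
    if K > matrix.n_samples:
        raise ParameterError("K exceeds the number of samples")
    g = matrix.dosage.astype(float)
    mask = matrix.dosage != MISSING
    g[~mask] = 0.0
    if K == 1:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(mask.sum(axis=0) > 0,
                         g.sum(axis=0) / np.maximum(2 * mask.sum(axis=0), 1),
                         0.5)
        P = np.clip(p, EPS, 1 - EPS)[None, :]
        Q = np.ones((matrix.n_samples, 1))
        ll = _loglik(g, mask, Q, P)
        return StructureResult(1, Q, P, ll, 0, seed, np.array([ll]))
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        Q, P, ll, n_iter, path = _em_once(g, mask, K, rng, tol, max_iter)
        if best is None or ll > best.log_likelihood:
            best = StructureResult(K, Q, P, ll, n_iter, seed, path)
    return best


@dataclass
class CVReport:
    errors: dict[int, float]
    selected_K: int
    folds: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.errors.items()),
                            columns=["K", "cv_error"])


def cross_validate(matrix: GenotypeMatrix, K_range, folds: int = 10,
                   seed: int = 0, n_starts: int = 2, tol: float = 1e-5,
                   max_iter: int = 500) -> CVReport:
    """Entry-masking K-fold cross-validation; argmin mean deviance.

    Non-missing genotype entries are partitioned into ``folds`` folds
    by seeded assignment; each fold is masked in turn, the model refit,
    and the masked entries scored by mean binomial deviance under the
    predicted allele frequencies f.
    """
    rng = np.random.default_rng(seed)
    obs = np.argwhere(matrix.dosage != MISSING)
    if len(obs) < folds * 10:
        raise ParameterError("too few non-missing entries for CV")
    for _attempt in range(10):
        assign = rng.integers(folds, size=len(obs))
        if len(np.unique(assign)) == folds:
            break
        logger.info("cross_validate: empty fold, re-drawing assignment")
    errors: dict[int, float] = {}
    for K in K_range:
        devs = []
        for f in range(folds):
            held = obs[assign == f]
            work = matrix.copy()
            work.dosage = work.dosage.copy()
            work.dosage[held[:, 0], held[:, 1]] = MISSING
            fit = admixture_em(work, K, seed=int(rng.integers(2 ** 31)),
                               tol=tol, max_iter=max_iter, n_starts=n_starts)
            fhat = np.clip(fit.Q @ fit.P, EPS, 1 - EPS)
            gh = matrix.dosage[held[:, 0], held[:, 1]].astype(float)
            fh = fhat[held[:, 0], held[:, 1]]
            dev = -2.0 * (gh * np.log(fh) + (2 - gh) * np.log(1 - fh))
            devs.append(dev.mean())
        errors[int(K)] = float(np.mean(devs))
    selected = min(errors, key=lambda k: (errors[k], k))
    return CVReport(errors=errors, selected_K=selected, folds=folds,
                    seed=seed)
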