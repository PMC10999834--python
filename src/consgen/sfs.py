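"""Unfolded SFS with hypergeometric projection and a stairway-style
piecewise-constant demographic fit.

The expected spectrum under a piecewise-constant diploid history uses
E[xi_i] = mu * L * E[B_i], where E[B_i] is the expected total branch
length subtending i of n leaves.  For a single epoch this is the exact
4*N/i; multi-epoch expectations are computed by seeded Monte-Carlo
averaging of coalescent intervals in rescaled time (common random
numbers keep the likelihood surface smooth for the optimizer).

The fit maximizes the composite Poisson log-likelihood
sum_i [xi_i ln lambda_i - lambda_i] over per-epoch sizes, with epoch
boundaries scanned on a log-spaced grid.  It is a deliberately small,
testable stand-in for stairway-plot-style inference: same inputs (an
unfolded SFS, mu, L, generation time), explicit parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar, minimize
from scipy.stats import hypergeom

from .core import DemographicModel, GenotypeMatrix, ParameterError
from .simulate import sample_coalescent_times


@dataclass
class SFS:
    """Unfolded spectrum at projected haploid size n_proj.

    ``counts[k-1]`` holds the (possibly fractional) number of sites
    with derived-allele count k, k = 1..n_proj-1.  ``L`` is the number
    of monomorphic-callable sites backing the spectrum.
    """

    n_proj: int
    counts: np.ndarray
    L: float
    dropped_low_coverage: int = 0
    projected_out: float = 0.0

    def __post_init__(self):
        if self.n_proj < 2:
            raise ParameterError("n_proj must be >= 2")
        if len(self.counts) != self.n_proj - 1:
            raise ParameterError("counts must have length n_proj - 1")
        if np.any(np.asarray(self.counts) < 0):
            raise ParameterError("spectrum entries must be non-negative")


def build_sfs(matrix: GenotypeMatrix, n_proj: int, L: float | None = None
              ) -> SFS:
    """Project a polarized matrix onto an n_proj-haploid unfolded SFS.

    Each segregating site with m >= n_proj called alleles and d derived
    copies contributes hypergeometric weights P(k | m, d, n_proj) to
    bins k = 1..n_proj-1; weight falling on k = 0 or k = n_proj
    (monomorphic after projection) is tracked in ``projected_out``, and
    sites with m < n_proj are dropped and counted.
    """
    if not matrix.polarized:
        raise ParameterError("build_sfs requires derived (polarized) coding")
    if n_proj < 2:
        raise ParameterError("n_proj must be >= 2")
    der, called = matrix.allele_counts()
    seg = (der > 0) & (der < called)
    counts = np.zeros(n_proj - 1)
    dropped = 0
    projected_out = 0.0
    ks = np.arange(n_proj + 1)
    for d, m in zip(der[seg], called[seg]):
        if m < n_proj:
            dropped += 1
            continue
        w = hypergeom.pmf(ks, m, d, n_proj)
        counts += w[1:n_proj]
        projected_out += w[0] + w[n_proj]
    if L is None:
        L = matrix.n_sites
    return SFS(n_proj=n_proj, counts=counts, L=float(L),
               dropped_low_coverage=dropped, projected_out=projected_out)


from functools import lru_cache


@lru_cache(maxsize=64)
def _subtend_weights(n: int) -> np.ndarray:
    """W[k-2, i-1] = P(a branch present while k lineages remain
    subtends i of the n leaves) = C(n-i-1, k-2) / C(n-1, k-1)."""
    from scipy.special import comb
    W = np.zeros((n - 1, n - 1))
    for k in range(2, n + 1):
        for i in range(1, n - k + 2):
            W[k - 2, i - 1] = comb(n - i - 1, k - 2) / comb(n - 1, k - 1)
    return W


def expected_branch_lengths(model: DemographicModel, n: int,
                            n_mc: int = 20_000, seed: int = 0,
                            exp_draws: np.ndarray | None = None) -> np.ndarray:
    """E[B_i] (generations), i = 1..n-1, under the model.

    Single-epoch models use the exact 4*N/i; otherwise coalescent
    intervals are Monte-Carlo averaged (``exp_draws`` may supply
    pre-drawn standard exponentials for common random numbers).
    """
    if n < 2 or n > 200:
        raise ParameterError("n must lie in [2, 200]")
    if model.n_epochs == 1:
        N = model.epochs[0][1]
        return 4.0 * N / np.arange(1, n)
    ks = np.arange(n, 1, -1)
    rates = ks * (ks - 1) / 2.0
    if exp_draws is None:
        rng = np.random.default_rng(seed)
        exp_draws = rng.exponential(1.0, size=(n_mc, n - 1))
    tau = np.cumsum(exp_draws / rates, axis=1)
    return _branch_lengths_from_tau(model, n, tau)


def _branch_lengths_from_tau(model: DemographicModel, n: int,
                             tau: np.ndarray) -> np.ndarray:
    """E[B_i] from pre-drawn rescaled coalescent event times ``tau``.

    ``tau`` (replicates x n-1) is parameter-free (the coalescence rates
    depend only on n), so an optimizer can reuse one draw across
    likelihood evaluations (common random numbers).
    """
    from .simulate import rescaled_to_generations
    t = rescaled_to_generations(tau, model)
    t0 = np.concatenate([np.zeros((t.shape[0], 1)), t[:, :-1]], axis=1)
    T_k = (t - t0).mean(axis=0)          # E[T_k], k = n..2
    W = _subtend_weights(n)              # rows k=2..n
    k_levels = np.arange(2, n + 1)
    # E[B_i] = sum_k k * E[T_k] * W[k, i]
    return (k_levels[:, None] * T_k[::-1, None] * W).sum(axis=0)


def expected_sfs(model: DemographicModel, n: int, L: float,
                 n_mc: int = 20_000, seed: int = 0,
                 exp_draws: np.ndarray | None = None) -> np.ndarray:
    """Expected counts per derived-allele-count bin (1..n-1)."""
    B = expected_branch_lengths(model, n, n_mc=n_mc, seed=seed,
                                exp_draws=exp_draws)
    return model.mu * L * B


@dataclass
class DemographyFit:
    model: DemographicModel
    log_likelihood: float
    converged: bool
    trace: list = field(default_factory=list)

    def step_table(self) -> pd.DataFrame:
        """Step-function table (start generations/years, diploid Ne)."""
        gt = self.model.generation_time_years
        rows, t = [], 0.0
        for dur, ne in self.model.epochs:
            rows.append((t, t * gt, ne))
            t += dur
        return pd.DataFrame(rows, columns=["start_gen", "start_years", "Ne"])


def _poisson_cll(obs: np.ndarray, lam: np.ndarray) -> float:
    lam = np.maximum(lam, 1e-300)
    return float(np.sum(obs * np.log(lam) - lam))


def fit_piecewise(sfs: SFS, n_epochs: int, mu: float, L: float | None = None,
                  generation_time_years: float = 30.0,
                  boundary_grid: np.ndarray | None = None,
                  n_mc: int = 10_000, n_starts: int = 3, seed: int = 0
                  ) -> DemographyFit:
    """Composite-likelihood fit of a piecewise-constant history.

    Epoch boundaries (for n_epochs >= 2) are scanned over a log-spaced
    grid of generations; per-epoch sizes are optimized numerically on a
    log scale.  Multi-start with seeded initializations; a fit that
    never converges is returned flagged rather than raised.
    """
    if not 1 <= n_epochs <= 5:
        raise ParameterError("n_epochs must lie in [1, 5]")
    if L is None:
        L = sfs.L
    n = sfs.n_proj
    obs = np.asarray(sfs.counts, dtype=float)
    rng = np.random.default_rng(seed)

    if n_epochs == 1:
        # lambda_i = 4 N mu L / i: closed-form ML in N
        i = np.arange(1, n)
        S_eff = obs.sum()
        denom = mu * L * 4.0 * np.sum(1.0 / i)
        N_hat = max(S_eff / denom, 2.0)
        model = DemographicModel([(np.inf, N_hat)], mu=mu,
                                 generation_time_years=generation_time_years)
        ll = _poisson_cll(obs, expected_sfs(model, n, L))
        return DemographyFit(model=model, log_likelihood=ll, converged=True,
                             trace=[("closed_form", N_hat, ll)])

    ks = np.arange(n, 1, -1)
    rates = ks * (ks - 1) / 2.0
    tau = np.cumsum(rng.exponential(1.0, size=(n_mc, n - 1)) / rates, axis=1)
    # rough Ne scale from Watterson on the spectrum, to center the grid
    theta_w_total = obs.sum() / np.sum(1.0 / np.arange(1, n))
    N_scale = max(theta_w_total / (4.0 * mu * L), 10.0)
    if boundary_grid is None:
        boundary_grid = np.geomspace(0.05 * 2 * N_scale, 4 * 2 * N_scale, 8)

    def objective(log10_sizes, bounds_gen):
        sizes = 10.0 ** np.asarray(log10_sizes)
        durs = list(np.diff([0.0, *bounds_gen])) + [np.inf]
        try:
            model = DemographicModel(
                [(d, s) for d, s in zip(durs, sizes)], mu=mu,
                generation_time_years=generation_time_years)
        except ParameterError:
            return 1e12
        lam = mu * L * _branch_lengths_from_tau(model, n, tau)
        return -_poisson_cll(obs, lam)

    best = None
    trace = []
    from itertools import combinations
    bgrids = list(combinations(boundary_grid, n_epochs - 1))
    for bounds_gen in bgrids:
        for _ in range(n_starts):
            x0 = np.log10(N_scale) + rng.normal(0, 0.5, size=n_epochs)
            res = minimize(objective, x0, args=(list(bounds_gen),),
                           method="Nelder-Mead",
                           options={"xatol": 2e-3, "fatol": 1e-3,
                                    "maxiter": 400})
            trace.append((bounds_gen, 10.0 ** res.x, -res.fun, res.success))
            if best is None or -res.fun > best[2]:
                best = (bounds_gen, 10.0 ** res.x, -res.fun, res.success)
    bounds_gen, sizes, ll, ok = best
    durs = list(np.diff([0.0, *bounds_gen])) + [np.inf]
    model = DemographicModel([(d, s) for d, s in zip(durs, sizes)], mu=mu,
                             generation_time_years=generation_time_years)
    return DemographyFit(model=model, log_likelihood=ll,
                         converged=bool(ok), trace=trace)


def sfs_to_frame(sfs: SFS) -> pd.DataFrame:
    return pd.DataFrame({"derived_count": np.arange(1, sfs.n_proj),
                         "sites": sfs.counts})
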