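"""Contemporary effective population size from linkage disequilibrium.

The LD method relates the mean squared allelic correlation among
unlinked loci to recent drift: after subtracting the sampling
expectation E[r^2 | S] for the observed (harmonic mean) sample size S,
the residual drift signal r^2' inverts to an Ne estimate through the
published random-mating regressions (separate coefficient sets for
S >= 30 and S < 30).  A delete-one-chromosome jackknife gives the
confidence interval on a log scale.

r^2 between unphased genotypes is the Burrows composite measure:
Delta-hat squared over allele-frequency variances corrected for the
observed homozygote excess, equivalently the squared Pearson
correlation of dosage vectors over individuals called at both loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MISSING, GenotypeMatrix, ParameterError

logger = __import__("logging").getLogger("consgen")


def prepare_loci(matrix: GenotypeMatrix, max_missing: float = 0.05,
                 thin_bp: int = 60_000, min_maf: float = 0.05
                 ) -> GenotypeMatrix:
    """Missingness/MAF filter followed by greedy positional thinning.

    Thinning keeps a site when it lies at least ``thin_bp`` bp from the
    previously kept site on the same chromosome (inclusive at exactly
    ``thin_bp``).
    """
    miss = (matrix.dosage == MISSING).mean(axis=0)
    alt, called = matrix.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, alt / np.maximum(called, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    keep = (miss <= max_missing) & (maf >= min_maf)
    cur = matrix.take_sites(keep)
    keep2 = np.zeros(cur.n_sites, dtype=bool)
    last_pos: dict[str, int] = {}
    for j in range(cur.n_sites):
        c = cur.chrom[j]
        if c not in last_pos or cur.pos[j] - last_pos[c] >= thin_bp:
            keep2[j] = True
            last_pos[c] = int(cur.pos[j])
    return cur.take_sites(keep2)


def burrows_r2(g1: np.ndarray, g2: np.ndarray) -> tuple[float, int]:
    """Burrows composite r^2 between two dosage vectors.

    Restricted to individuals called at both loci; returns
    ``(r2, n_used)``; NaN r2 when either locus is monomorphic in the
    shared individuals.
    """
    ok = (g1 != MISSING) & (g2 != MISSING)
    n = int(ok.sum())
    if n < 2:
        return float("nan"), n
    a = g1[ok].astype(float)
    b = g2[ok].astype(float)
    pa = a.mean() / 2.0
    pb = b.mean() / 2.0
    delta = (a * b).sum() / (2.0 * n) - 2.0 * pa * pb
    da = (a == 2).mean() - pa ** 2   # homozygote excess locus A
    db = (b == 2).mean() - pb ** 2
    va = pa * (1 - pa) + da
    vb = pb * (1 - pb) + db
    if va <= 0 or vb <= 0:
        return float("nan"), n
    return float(delta ** 2 / (va * vb)), n


def pairwise_r2_burrows(matrix: GenotypeMatrix,
                        inter_chromosome_only: bool = False,
                        min_dist: int | None = None):
    """Mean Burrows r^2 over locus pairs.

    Pairs are restricted to different chromosomes when
    ``inter_chromosome_only``; otherwise same-chromosome pairs closer
    than ``min_dist`` (when given) are excluded so the unlinked-loci
    assumption approximately holds.  Returns
    ``(mean_r2, n_pairs, harmonic_mean_S, per_pair)`` with ``per_pair``
    a list of (chrom_i, chrom_j, r2, n) diagnostics.
    """
    L = matrix.n_sites
    if L < 2:
        raise ParameterError("need >= 2 loci")
    r2s, ns, pairs = [], [], []
    for i in range(L):
        for j in range(i + 1, L):
            same = matrix.chrom[i] == matrix.chrom[j]
            if inter_chromosome_only and same:
                continue
            if same and min_dist is not None and \
                    abs(int(matrix.pos[j]) - int(matrix.pos[i])) <= min_dist:
                continue
            r2, n = burrows_r2(matrix.dosage[:, i], matrix.dosage[:, j])
            if np.isnan(r2):
                continue
            r2s.append(r2)
            ns.append(n)
            pairs.append((matrix.chrom[i], matrix.chrom[j], r2, n))
    if not r2s:
        return float("nan"), 0, float("nan"), []
    mean_r2 = float(np.mean(r2s))
    harm_S = float(len(ns) / np.sum(1.0 / np.asarray(ns, dtype=float)))
    return mean_r2, len(r2s), harm_S, pairs


def expected_r2_sampling(S: float) -> float:
    """E[r^2] under no drift for (harmonic mean) sample size S
    (random mating regressions; separate small/large-S coefficients)."""
    if S < 4:
        raise ParameterError("sample size must be >= 4")
    if S >= 30:
        return 1.0 / S + 3.19 / S ** 2
    return 0.0018 + 0.907 / S + 4.44 / S ** 2


@dataclass
class NeEstimate:
    ne: float                   # inf when no drift signal
    ci_low: float
    ci_high: float
    mean_r2: float
    r2_drift: float
    sample_size: float
    n_pairs: int
    finite: bool


def _invert_ne(r2_drift: float, S: float) -> float:
    """Published quadratic inversion of the drift r^2 to Ne."""
    if r2_drift <= 0:
        return float("inf")
    if S >= 30:
        disc = 1.0 / 9.0 - 2.76 * r2_drift
        third = 1.0 / 3.0
    else:
        disc = 0.308 ** 2 - 2.08 * r2_drift
        third = 0.308
    if disc < 0:
        disc = 0.0
    return (third + np.sqrt(disc)) / (2.0 * r2_drift)


def estimate_ne(mean_r2: float, S: float, n_pairs: int = 0) -> NeEstimate:
    """Point estimate of contemporary Ne from mean r^2 and sample size."""
    r2_drift = mean_r2 - expected_r2_sampling(S)
    ne = _invert_ne(r2_drift, S)
    return NeEstimate(ne=ne, ci_low=float("nan"), ci_high=float("nan"),
                      mean_r2=mean_r2, r2_drift=r2_drift, sample_size=S,
                      n_pairs=n_pairs, finite=np.isfinite(ne))


def jackknife_ci(matrix: GenotypeMatrix, inter_chromosome_only: bool = False,
                 min_dist: int | None = None, z: float = 1.96) -> NeEstimate:
    """Ne with delete-one-chromosome jackknife CI (log scale).

    Blocks are chromosomes; a deletion leaving no informative pairs is
    skipped with a log entry.  With < 3 blocks the CI is undefined
    (NaN) and flagged by the returned estimate.
    """
    mean_r2, n_pairs, S, per_pair = pairwise_r2_burrows(
        matrix, inter_chromosome_only, min_dist)
    point = estimate_ne(mean_r2, S, n_pairs)
    blocks = list(dict.fromkeys(matrix.chrom.tolist()))
    if len(blocks) < 3:
        logger.warning("jackknife_ci: < 3 chromosome blocks, CI undefined")
        return point
    chrom_i = np.array([p[0] for p in per_pair], dtype=object)
    chrom_j = np.array([p[1] for p in per_pair], dtype=object)
    r2_arr = np.array([p[2] for p in per_pair])
    n_arr = np.array([p[3] for p in per_pair], dtype=float)
    loo = []
    for c in blocks:
        keep = (chrom_i != c) & (chrom_j != c)
        if keep.sum() == 0:
            logger.info("jackknife_ci: block %s deletion has no pairs", c)
            continue
        m = float(r2_arr[keep].mean())
        s = float(keep.sum() / np.sum(1.0 / n_arr[keep]))
        loo.append(estimate_ne(m, s, int(keep.sum())).ne)
    loo = np.array([x for x in loo if np.isfinite(x)])
    if len(loo) < 3 or not point.finite:
        return point
    logs = np.log(loo)
    B = len(logs)
    var = (B - 1) / B * np.sum((logs - logs.mean()) ** 2)
    se = np.sqrt(var)
    lo = float(np.exp(np.log(point.ne) - z * se))
    hi = float(np.exp(np.log(point.ne) + z * se))
    return NeEstimate(ne=point.ne, ci_low=lo, ci_high=hi,
                      mean_r2=point.mean_r2, r2_drift=point.r2_drift,
                      sample_size=point.sample_size, n_pairs=point.n_pairs,
                      finite=point.finite)
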