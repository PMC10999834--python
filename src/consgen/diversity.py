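"""Windowed diversity estimators, heterozygosity, FST and LD decay.

Estimators follow the classical count-based definitions: Watterson's
theta from segregating sites, nucleotide diversity as unbiased mean
pairwise difference, Tajima's D and Fu & Li's D with their published
variance constants.  Missing genotypes are handled with per-site
called-allele counts; the D statistics use one representative n per
window (the median per-site count) for their variance constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, ParameterError, PopulationMap

WINDOW = 20_000
STEP = 10_000


def harmonic(n: int, power: int = 1) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i^power."""
    i = np.arange(1, n)
    return float(np.sum(1.0 / i ** power))


def _harmonic_lookup(ns: np.ndarray) -> np.ndarray:
    """Vectorized a_{n} = sum_{i<n} 1/i for an integer array."""
    top = int(ns.max()) if len(ns) else 2
    table = np.concatenate([[0.0, 0.0],
                            np.cumsum(1.0 / np.arange(1, top))])
    return table[ns]


def chrom_site_index(matrix: GenotypeMatrix) -> dict[str, np.ndarray]:
    """chromosome -> array of site indices, built in one pass."""
    out: dict[str, list[int]] = {}
    for j, c in enumerate(matrix.chrom.tolist()):
        out.setdefault(c, []).append(j)
    return {c: np.asarray(v) for c, v in out.items()}


def tajima_constants(n: int) -> dict[str, float]:
    """Variance constants of Tajima's D at sample size n (alleles)."""
    if n < 4:
        raise ParameterError("Tajima's D needs n >= 4")
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": c1 / a1, "e2": c2 / (a1 ** 2 + a2)}


def fu_li_constants(n: int, starred: bool = False) -> dict[str, float]:
    """Variance constants of Fu & Li's D (outgroup) or D* (folded)."""
    if n < 3:
        raise ParameterError("Fu & Li statistics need n >= 3")
    an = harmonic(n)
    bn = harmonic(n, 2)
    cn = 1.0 if n == 2 else 2.0 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    if not starred:
        vd = 1.0 + (an ** 2 / (bn + an ** 2)) * (cn - (n + 1) / (n - 1.0))
        ud = an - 1.0 - vd
        return {"an": an, "bn": bn, "cn": cn, "u": ud, "v": vd}
    an1 = an + 1.0 / n  # a_{n+1}
    dn = cn + (n - 2) / ((n - 1.0) ** 2) + (2.0 / (n - 1)) * (
        1.5 - (2 * an1 - 3) / (n - 2.0) - 1.0 / n)
    vds = ((n / (n - 1.0)) ** 2 * bn + an ** 2 * dn
           - 2 * (n * an * (an + 1)) / ((n - 1.0) ** 2)) / (an ** 2 + bn)
    uds = (n / (n - 1.0)) * (an - n / (n - 1.0)) - vds
    return {"an": an, "bn": bn, "cn": cn, "dn": dn, "u": uds, "v": vds}


def _site_arrays(matrix: GenotypeMatrix, derived: bool):
    """Per-site (focal allele count, called allele count).

    ``derived=True`` requires a polarized matrix; otherwise ALT counts
    are used (sufficient for the frequency-symmetric estimators).
    """
    alt, called = matrix.allele_counts()
    return alt, called


def per_site_pi(matrix: GenotypeMatrix) -> np.ndarray:
    """Unbiased per-site heterozygosity 2*d*(n-d)/(n*(n-1))."""
    d, n = _site_arrays(matrix, derived=False)
    out = np.zeros(matrix.n_sites)
    ok = n >= 2
    out[ok] = 2.0 * d[ok] * (n[ok] - d[ok]) / (n[ok] * (n[ok] - 1.0))
    return out


def watterson_theta(matrix: GenotypeMatrix, callable_sites: int) -> float:
    """Watterson's theta per site: sum over segregating sites of
    1/a_{n_s}, divided by the number of callable sites."""
    if callable_sites <= 0:
        return float("nan")
    d, n = _site_arrays(matrix, derived=False)
    seg = (d > 0) & (d < n)
    if not seg.any():
        return 0.0
    a = _harmonic_lookup(n[seg])
    return float(np.sum(1.0 / a) / callable_sites)


def nucleotide_diversity(matrix: GenotypeMatrix, callable_sites: int) -> float:
    """Nucleotide diversity per site (mean pairwise differences)."""
    if callable_sites <= 0:
        return float("nan")
    return float(per_site_pi(matrix).sum() / callable_sites)


def _window_d_stats(d: np.ndarray, n: np.ndarray):
    """(Tajima's D, Fu&Li D, variant) from per-site derived/called counts.

    ``d`` must be derived counts for the outgroup Fu & Li variant to be
    meaningful; when the matrix is unpolarized the starred variant is
    the one to report.
    """
    seg = (d > 0) & (d < n)
    S = int(seg.sum())
    if S == 0:
        return np.nan, np.nan
    n_rep = int(np.median(n[seg]))
    if n_rep < 4:
        return np.nan, np.nan
    tc = tajima_constants(n_rep)
    pi_count = float(np.sum(2.0 * d[seg] * (n[seg] - d[seg])
                            / (n[seg] * (n[seg] - 1.0))))
    tw_count = S / tc["a1"]
    var = tc["e1"] * S + tc["e2"] * S * (S - 1)
    taj = (pi_count - tw_count) / np.sqrt(var) if var > 0 else np.nan
    return taj, (pi_count, tw_count, S, n_rep)


def tajimas_d(matrix: GenotypeMatrix) -> float:
    d, n = _site_arrays(matrix, derived=False)
    taj, _ = _window_d_stats(d, n)
    return taj


def fu_li_d(matrix: GenotypeMatrix, use_ancestral: bool | None = None
            ) -> tuple[float, str]:
    """Fu & Li's D; uses derived singletons when polarization is
    available (outgroup variant), else minor-allele singletons (D*).

    Returns ``(statistic, variant)`` with variant "D" or "D*".
    """
    d, n = _site_arrays(matrix, derived=False)
    if use_ancestral is None:
        use_ancestral = matrix.polarized
    return _fu_li_from_counts(d, n, use_ancestral)


def _fu_li_from_counts(d: np.ndarray, n: np.ndarray, use_ancestral: bool
                       ) -> tuple[float, str]:
    seg = (d > 0) & (d < n)
    S = int(seg.sum())
    if S == 0:
        return np.nan, "D" if use_ancestral else "D*"
    n_rep = int(np.median(n[seg]))
    if n_rep < 3:
        return np.nan, "D" if use_ancestral else "D*"
    if use_ancestral:
        eta_e = int(np.sum(seg & (d == 1)))
        k = fu_li_constants(n_rep)
        var = k["u"] * S + k["v"] * S * S
        stat = (S - k["an"] * eta_e) / np.sqrt(var) if var > 0 else np.nan
        return float(stat), "D"
    eta_s = int(np.sum(seg & ((d == 1) | (d == n - 1))))
    k = fu_li_constants(n_rep, starred=True)
    var = k["u"] * S + k["v"] * S * S
    nn = n_rep / (n_rep - 1.0)
    stat = (nn * S - k["an"] * eta_s) / np.sqrt(var) if var > 0 else np.nan
    return float(stat), "D*"


def chromosome_lengths(matrix: GenotypeMatrix) -> dict[str, int]:
    return {c: int(matrix.pos[matrix.chrom == c].max()) + 1
            for c in dict.fromkeys(matrix.chrom.tolist())}


def window_stats(matrix: GenotypeMatrix, window: int = WINDOW,
                 step: int = STEP,
                 chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Sliding-window diversity table (0-based half-open windows).

    Callable sites per window are taken as the window span, the
    simulated-data convention where every position is callable; supply
    real callable counts by post-processing if they differ.
    """
    if chrom_lengths is None:
        chrom_lengths = chromosome_lengths(matrix)
    d_all, n_all = _site_arrays(matrix, derived=False)
    groups = chrom_site_index(matrix)
    rows = []
    for c, length in chrom_lengths.items():
        on = groups.get(c, np.array([], dtype=int))
        pos = matrix.pos[on]
        start = 0
        while start < length:
            end = min(start + window, length)
            lo, hi = np.searchsorted(pos, [start, end])
            sel = on[lo:hi]
            callable_sites = end - start
            d, n = d_all[sel], n_all[sel]
            seg = (d > 0) & (d < n)
            S = int(seg.sum())
            singles = int(np.sum(seg & (d == 1))) if matrix.polarized else \
                int(np.sum(seg & ((d == 1) | (d == n - 1))))
            a = _harmonic_lookup(n[seg]) if S else np.array([])
            tw = float(np.sum(1.0 / a) / callable_sites) if S else 0.0
            pi_sites = (2.0 * d[seg] * (n[seg] - d[seg])
                        / (n[seg] * np.maximum(n[seg] - 1.0, 1)))
            pi = float(pi_sites.sum() / callable_sites)
            taj, _ = _window_d_stats(d, n)
            fl, variant = _fu_li_from_counts(d, n, matrix.polarized)
            rows.append((c, start, end, callable_sites, S, singles,
                         tw, pi, taj, fl, variant))
            if end == length:
                break
            start += step
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "callable_sites", "S", "singletons",
        "theta_w", "theta_pi", "tajimas_d", "fu_li_d", "fu_li_variant"])


def individual_heterozygosity(matrix: GenotypeMatrix,
                              callable_denominator: int,
                              popmap: PopulationMap | None = None):
    """Per-sample heterozygous-call rate over a callable denominator."""
    if callable_denominator <= 0:
        raise ParameterError("callable denominator must be positive")
    het = (matrix.dosage == 1).sum(axis=1) / callable_denominator
    df = pd.DataFrame({"sample": matrix.sample_ids, "het_rate": het})
    if popmap is not None:
        df["population"] = [popmap.mapping[s] for s in matrix.sample_ids]
    return df


@dataclass
class FstResult:
    pop1: str
    pop2: str
    fst: float
    estimator: str
    n_sites: int


def _pop_freqs(matrix: GenotypeMatrix, idx: np.ndarray):
    sub = matrix.dosage[idx]
    called = sub != MISSING
    n = 2 * called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    return alt, n


def hudson_fst_components(matrix: GenotypeMatrix, idx1, idx2):
    """Per-site Hudson numerator/denominator arrays (NaN where undefined)."""
    a1, n1 = _pop_freqs(matrix, idx1)
    a2, n2 = _pop_freqs(matrix, idx2)
    ok = (n1 >= 2) & (n2 >= 2)
    p1 = np.where(ok, a1 / np.maximum(n1, 1), np.nan)
    p2 = np.where(ok, a2 / np.maximum(n2, 1), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
               - p2 * (1 - p2) / np.maximum(n2 - 1, 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num[~ok] = np.nan
    den[~ok] = np.nan
    return num, den


def _wc_fst(matrix: GenotypeMatrix, idx1, idx2) -> float:
    """Weir & Cockerham two-population theta (ratio of averages)."""
    a1, n1 = _pop_freqs(matrix, idx1)
    a2, n2 = _pop_freqs(matrix, idx2)
    ok = (n1 >= 2) & (n2 >= 2)
    p1, p2 = a1 / np.maximum(n1, 1), a2 / np.maximum(n2, 1)
    r = 2.0
    nbar = (n1 + n2) / 2.0
    nc = ((n1 + n2) - (n1 ** 2 + n2 ** 2) / np.maximum(n1 + n2, 1)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / np.maximum(n1 + n2, 1)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * 2 * p1 * (1 - p1) * n1 / np.maximum(n1 - 1, 1)
            + n2 * 2 * p2 * (1 - p2) * n2 / np.maximum(n2 - 1, 1)) \
        / np.maximum(n1 + n2, 1)
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                     / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    cc = hbar / 2
    num, den = a, a + b + cc
    num[~ok] = np.nan
    den[~ok] = np.nan
    return float(np.nansum(num) / np.nansum(den))


def pairwise_fst(matrix: GenotypeMatrix, popmap: PopulationMap,
                 estimator: str = "hudson") -> list[FstResult]:
    """Genome-wide pairwise FST (ratio of averages over sites)."""
    groups = popmap.sample_index(matrix)
    pops = sorted(groups)
    out = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            idx1, idx2 = groups[pops[i]], groups[pops[j]]
            if estimator == "hudson":
                num, den = hudson_fst_components(matrix, idx1, idx2)
                fst = float(np.nansum(num) / np.nansum(den))
                n_used = int(np.sum(~np.isnan(den)))
            elif estimator == "wc":
                fst = _wc_fst(matrix, idx1, idx2)
                n_used = matrix.n_sites
            else:
                raise ParameterError(f"unknown FST estimator {estimator!r}")
            out.append(FstResult(pops[i], pops[j], fst, estimator, n_used))
    return out


def ld_decay(matrix: GenotypeMatrix, max_dist: int = 500_000,
             bin_width: int = 1_000) -> pd.DataFrame:
    """Mean genotype r^2 by pairwise distance bin (intra-chromosomal).

    r^2 is the squared Pearson correlation of mean-imputed dosages,
    which equals the Burrows composite measure in the absence of
    missing data.  No monotone smoothing is applied.
    """
    from .filtering import _imputed_dosage, _pairwise_r2
    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    dose = _imputed_dosage(matrix)
    for c in dict.fromkeys(matrix.chrom.tolist()):
        idx = np.where(matrix.chrom == c)[0]
        if len(idx) < 2:
            continue
        pos = matrix.pos[idx]
        r2 = _pairwise_r2(dose[:, idx])
        dist = np.abs(pos[:, None] - pos[None, :])
        iu = np.triu_indices(len(idx), k=1)
        d, r = dist[iu], r2[iu]
        ok = d < max_dist
        b = (d[ok] // bin_width).astype(int)
        np.add.at(sums, b, r[ok])
        np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "dist_low": np.arange(n_bins) * bin_width,
        "dist_high": (np.arange(n_bins) + 1) * bin_width,
        "mean_r2": mean_r2, "n_pairs": counts})


def fold_difference(value: float, reference: float) -> float:
    """How many times larger ``value`` is than ``reference``."""
    if reference <= 0:
        raise ParameterError("reference must be positive")
    return value / reference
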