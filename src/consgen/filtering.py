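"""Variant filter chain and LD pruning.

The stages mirror a standard resequencing workflow: per-genotype
quality/depth masking, site-level filters applied in the fixed order
depth -> biallelic/SNP -> missingness -> minor allele frequency, greedy
window LD pruning, and a neutrality mask removing sites within a flank
of annotated genes.  Every stage records entering/exiting site counts
in a :class:`FilterReport`, and re-running a stage on its own output is
a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

logger = __import__("logging").getLogger("consgen")


@dataclass
class FilterReport:
    """Per-stage site bookkeeping: (stage, entering, removed, params)."""

    stages: list[tuple[str, int, int, str]] = field(default_factory=list)

    def add(self, stage: str, entering: int, removed: int, params: str = ""):
        if removed < 0 or removed > entering:
            raise ValueError("removed count outside [0, entering]")
        self.stages.append((stage, entering, removed, params))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s, n, r, n - r, p) for s, n, r, p in self.stages],
            columns=["stage", "entering", "removed", "exiting", "params"])


def mask_genotypes(matrix: GenotypeMatrix, min_gq: int = 20,
                   min_dp: int = 5) -> GenotypeMatrix:
    """Set genotypes with GQ < min_gq or DP < min_dp to missing.

    Cells lacking a GQ/DP value (or matrices without those fields) are
    left untouched and a warning is logged.
    """
    out = matrix.copy()
    bad = np.zeros_like(out.dosage, dtype=bool)
    if matrix.gq is None and matrix.dp is None:
        logger.warning("mask_genotypes: no GQ or DP fields present; no-op")
        return out
    if matrix.gq is not None:
        bad |= (matrix.gq != MISSING) & (matrix.gq < min_gq)
    else:
        logger.warning("mask_genotypes: GQ absent, quality rule skipped")
    if matrix.dp is not None:
        bad |= (matrix.dp != MISSING) & (matrix.dp < min_dp)
    else:
        logger.warning("mask_genotypes: DP absent, depth rule skipped")
    out.dosage = np.where(bad, MISSING, out.dosage).astype(np.int16)
    return out


def filter_sites(matrix: GenotypeMatrix, keep_biallelic_snps: bool = True,
                 max_missing: float = 0.20, min_maf: float = 0.05,
                 total_depth_range: tuple[int, int] | None = (100, 600),
                 report: FilterReport | None = None
                 ) -> tuple[GenotypeMatrix, FilterReport]:
    """Site-level filters in the order depth -> SNP -> missingness -> MAF.

    Depth keeps sites whose summed DP across samples lies in the
    inclusive range ``total_depth_range`` (removal is strict < low or
    > high).  Missingness removes sites with a missing-genotype rate
    strictly above ``max_missing``; MAF removes sites with minor allele
    frequency (from non-missing dosages) strictly below ``min_maf``.
    """
    if report is None:
        report = FilterReport()
    cur = matrix

    if total_depth_range is not None and cur.dp is not None:
        lo, hi = total_depth_range
        depth = np.where(cur.dp == MISSING, 0, cur.dp).sum(axis=0)
        keep = (depth >= lo) & (depth <= hi)
        report.add("total_depth", cur.n_sites, int((~keep).sum()),
                   f"[{lo},{hi}] summed DP")
        cur = cur.take_sites(keep)
    else:
        report.add("total_depth", cur.n_sites, 0, "skipped (no DP)")

    if keep_biallelic_snps:
        keep = np.array([len(r) == 1 and len(a) == 1 and r != a and a != "N"
                         for r, a in zip(cur.ref, cur.alt)])
        report.add("biallelic_snp", cur.n_sites, int((~keep).sum()), "")
        cur = cur.take_sites(keep)

    miss_rate = (cur.dosage == MISSING).mean(axis=0) if cur.n_samples else \
        np.zeros(cur.n_sites)
    keep = miss_rate <= max_missing
    report.add("missingness", cur.n_sites, int((~keep).sum()),
               f"max {max_missing:g}")
    cur = cur.take_sites(keep)

    alt, called = cur.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, alt / np.maximum(called, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    keep = (called > 0) & (maf >= min_maf)
    report.add("maf", cur.n_sites, int((~keep).sum()), f"min {min_maf:g}")
    cur = cur.take_sites(keep)
    if cur.n_sites == 0:
        logger.warning("filter_sites: no sites survive the chain")
    return cur, report


def _imputed_dosage(matrix: GenotypeMatrix) -> np.ndarray:
    """Float dosages with missing cells replaced by the site mean."""
    d = matrix.dosage.astype(float)
    d[matrix.dosage == MISSING] = np.nan
    means = np.nanmean(d, axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    idx = np.where(np.isnan(d))
    d[idx] = means[idx[1]]
    return d


def _pairwise_r2(dose: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns."""
    x = dose - dose.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.nan
    c = (x.T @ x) / len(x)
    r = c / np.outer(sd, sd)
    return np.nan_to_num(r ** 2)


def ld_prune(matrix: GenotypeMatrix, window_sites: int = 50,
             step_sites: int = 10, r2_threshold: float = 0.2
             ) -> GenotypeMatrix:
    """Greedy window LD pruning on mean-imputed genotype correlation.

    Within each ``window_sites``-site window (sliding by
    ``step_sites`` sites, per chromosome) every pair with r^2 strictly
    above the threshold drops the later-position site.  Deterministic.
    """
    keep_global = np.ones(matrix.n_sites, dtype=bool)
    dose = _imputed_dosage(matrix)
    for c in dict.fromkeys(matrix.chrom.tolist()):
        idx = np.where(matrix.chrom == c)[0]
        removed = np.zeros(len(idx), dtype=bool)
        start = 0
        while start < len(idx):
            window = np.arange(start, min(start + window_sites, len(idx)))
            alive = window[~removed[window]]
            if len(alive) > 1:
                r2 = _pairwise_r2(dose[:, idx[alive]])
                for a in range(len(alive)):
                    if removed[alive[a]]:
                        continue
                    for b in range(a + 1, len(alive)):
                        if removed[alive[b]]:
                            continue
                        if r2[a, b] > r2_threshold:
                            removed[alive[b]] = True
            if start + window_sites >= len(idx):
                break
            start += step_sites
        keep_global[idx[removed]] = False
    return matrix.take_sites(keep_global)


def merge_intervals(intervals):
    """Merge overlapping/adjacent (chrom, start, end) half-open intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    merged = []
    for c, ivs in by_chrom.items():
        ivs.sort()
        cs, ce = ivs[0]
        for s, e in ivs[1:]:
            if s <= ce:
                ce = max(ce, e)
            else:
                merged.append((c, cs, ce))
                cs, ce = s, e
        merged.append((c, cs, ce))
    return merged


def neutral_mask(matrix: GenotypeMatrix, gene_intervals,
                 flank: int = 5_000) -> GenotypeMatrix:
    """Drop sites within ``flank`` bp of any gene interval.

    Intervals are 0-based half-open on the matrix coordinate system;
    overlapping intervals are merged silently.
    """
    if not gene_intervals:
        return matrix.copy()
    remove = np.zeros(matrix.n_sites, dtype=bool)
    for c, s, e in merge_intervals(gene_intervals):
        on = matrix.chrom == c
        remove |= on & (matrix.pos >= s - flank) & (matrix.pos < e + flank)
    return matrix.take_sites(~remove)
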