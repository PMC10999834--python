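"""Derived deleterious-allele load: site classes, HoDA/HeDA counts,
population sharing partitions and DAF-based summaries.

Sites are classified from an annotation table by the SIFT convention:
nonsynonymous with score < 0.05 is deleterious, nonsynonymous with
score >= 0.05 tolerated.  Load is counted on derived (polarized)
dosages: HoDA = sites homozygous for the derived deleterious allele,
HeDA = heterozygous.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import (MISSING, AnnotationTable, GenotypeMatrix, ParameterError,
                   PopulationMap)

logger = __import__("logging").getLogger("consgen")

DELETERIOUS_SCORE = 0.05


def classify_sites(ann: AnnotationTable,
                   threshold: float = DELETERIOUS_SCORE) -> np.ndarray:
    """Per-site class in {synonymous, tolerated, deleterious, other}.

    Deleterious iff nonsynonymous with score strictly below the
    threshold; nonsynonymous sites without a score become "other" (and
    are logged); scores on synonymous sites are ignored with a warning.
    """
    out = np.full(ann.n_sites, "other", dtype=object)
    has_score = ~np.isnan(ann.score)
    syn = ann.klass == "synonymous"
    nonsyn = ann.klass == "nonsynonymous"
    out[syn] = "synonymous"
    if np.any(syn & has_score):
        logger.warning("classify_sites: scores on %d synonymous sites ignored",
                       int(np.sum(syn & has_score)))
    scored = nonsyn & has_score
    out[scored & (ann.score < threshold)] = "deleterious"
    out[scored & (ann.score >= threshold)] = "tolerated"
    if np.any(nonsyn & ~has_score):
        logger.warning("classify_sites: %d nonsynonymous sites lack scores",
                       int(np.sum(nonsyn & ~has_score)))
    return out


def count_load(matrix: GenotypeMatrix, site_classes: np.ndarray,
               popmap: PopulationMap | None = None) -> pd.DataFrame:
    """Per-sample HoDA/HeDA over deleterious sites (missing ignored)."""
    if not matrix.polarized:
        raise ParameterError("count_load requires derived (polarized) coding")
    if len(site_classes) != matrix.n_sites:
        raise ParameterError("site class array length != n_sites")
    dele = site_classes == "deleterious"
    sub = matrix.dosage[:, dele]
    hoda = (sub == 2).sum(axis=1)
    heda = (sub == 1).sum(axis=1)
    df = pd.DataFrame({"sample": matrix.sample_ids,
                       "HoDA": hoda, "HeDA": heda})
    if popmap is not None:
        df["population"] = [popmap.mapping[s] for s in matrix.sample_ids]
    return df


def population_presence(matrix: GenotypeMatrix, site_classes: np.ndarray,
                        popmap: PopulationMap,
                        mode: str = "any") -> pd.DataFrame:
    """Deleterious-site x population presence table.

    ``mode="any"`` marks a population carrying >= 1 derived allele at
    the site; ``mode="hoda"`` requires >= 1 derived-homozygous
    individual (the HoDA reading of a sharing diagram).
    """
    if mode not in ("any", "hoda"):
        raise ParameterError("mode must be 'any' or 'hoda'")
    dele = np.where(site_classes == "deleterious")[0]
    groups = popmap.sample_index(matrix)
    pops = sorted(groups)
    data = {}
    for p in pops:
        sub = matrix.dosage[np.ix_(groups[p], dele)]
        present = (sub == 2).any(axis=0) if mode == "hoda" else \
            (sub >= 1).any(axis=0)
        data[p] = present
    df = pd.DataFrame(data)
    df.insert(0, "chrom", matrix.chrom[dele])
    df.insert(1, "pos", matrix.pos[dele])
    return df


@dataclass
class SharingPartition:
    """Venn-region counts over populations for deleterious derived alleles."""

    region_counts: dict[frozenset, int]
    private_fraction: dict[str, float]
    n_alleles: int

    def shared_by_all(self, pops) -> int:
        return self.region_counts.get(frozenset(pops), 0)


def sharing_partition(presence: pd.DataFrame) -> SharingPartition:
    """Partition present alleles into the 2^P - 1 Venn regions."""
    pops = [c for c in presence.columns if c not in ("chrom", "pos")]
    if len(pops) < 2:
        raise ParameterError("sharing requires >= 2 populations")
    flags = presence[pops].to_numpy(dtype=bool)
    anywhere = flags.any(axis=1)
    regions: dict[frozenset, int] = {}
    for row in flags[anywhere]:
        key = frozenset(p for p, f in zip(pops, row) if f)
        regions[key] = regions.get(key, 0) + 1
    private = {}
    for p in pops:
        in_p = int(flags[:, pops.index(p)].sum())
        only_p = regions.get(frozenset([p]), 0)
        private[p] = only_p / in_p if in_p else float("nan")
    return SharingPartition(region_counts=regions, private_fraction=private,
                            n_alleles=int(anywhere.sum()))


def homozygous_fraction(n_homozygous: int, n_deleterious: int) -> float:
    """Fraction of deleterious sites carried homozygous (species level)."""
    if n_deleterious <= 0:
        raise ParameterError("no deleterious sites: fraction undefined")
    if not 0 <= n_homozygous <= n_deleterious:
        raise ParameterError("homozygous count outside [0, n_deleterious]")
    return n_homozygous / n_deleterious


@dataclass
class LoadSummary:
    per_sample: pd.DataFrame
    n_deleterious: int
    n_synonymous: int
    n_tolerated: int
    frac_daf_below: float
    daf_threshold: float
    n_homozygous_sites: int
    frac_homozygous: float
    daf_spectrum: pd.DataFrame


def load_summary(matrix: GenotypeMatrix, site_classes: np.ndarray,
                 popmap: PopulationMap | None = None,
                 daf_threshold: float = 0.05,
                 restrict_homozygous_to_common: bool = False) -> LoadSummary:
    """Species-level load summary.

    A deleterious site counts as "homozygous" when at least one
    individual is derived-homozygous there, optionally restricted to
    sites with DAF > ``daf_threshold``.  Fractions are NaN-flagged when
    there are no deleterious sites.
    """
    if not matrix.polarized:
        raise ParameterError("load_summary requires polarized coding")
    per_sample = count_load(matrix, site_classes, popmap)
    dele = site_classes == "deleterious"
    n_del = int(dele.sum())
    der, called = matrix.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        daf = np.where(called > 0, der / np.maximum(called, 1), np.nan)
    if n_del == 0:
        logger.warning("load_summary: zero deleterious sites")
        empty = pd.DataFrame({"daf": [], "sites": []})
        return LoadSummary(per_sample, 0,
                           int(np.sum(site_classes == "synonymous")),
                           int(np.sum(site_classes == "tolerated")),
                           float("nan"), daf_threshold, 0, float("nan"), empty)
    daf_del = daf[dele]
    frac_below = float(np.nanmean(daf_del < daf_threshold))
    hom_any = (matrix.dosage[:, dele] == 2).any(axis=0)
    if restrict_homozygous_to_common:
        hom_any = hom_any & (daf_del > daf_threshold)
    bins = np.linspace(0, 1, 21)
    hist, _ = np.histogram(daf_del[~np.isnan(daf_del)], bins=bins)
    spectrum = pd.DataFrame({"daf": bins[:-1], "sites": hist})
    return LoadSummary(
        per_sample=per_sample,
        n_deleterious=n_del,
        n_synonymous=int(np.sum(site_classes == "synonymous")),
        n_tolerated=int(np.sum(site_classes == "tolerated")),
        frac_daf_below=frac_below,
        daf_threshold=daf_threshold,
        n_homozygous_sites=int(hom_any.sum()),
        frac_homozygous=float(hom_any.sum() / n_del),
        daf_spectrum=spectrum)
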