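"""Core in-memory containers shared by every pipeline stage.

Coordinates are 0-based half-open internally; VCF input/output converts
to and from 1-based positions at the boundary.  Diploid genotypes are
stored as alternate/derived allele dosages in {0, 1, 2}, with ``-1``
for a missing call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

MISSING = -1


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ParameterError(ValueError):
    """Raised when a simulation or estimator parameter is invalid."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-sites diploid dosage matrix.

    Attributes
    ----------
    sample_ids : list of str
    chrom : array of str, per site
    pos : array of int, 0-based site positions
    ref, alt : arrays of single-character alleles
    ancestral : array of single characters; one of ref/alt, or ``'N'``
        when the site is unpolarized
    dosage : (n_samples, n_sites) int16 array of ALT (or derived, after
        polarization) allele counts; ``-1`` marks a missing genotype
    gq, dp : optional per-genotype quality / depth arrays, same shape
    polarized : True once dosages count derived rather than ALT alleles
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    ancestral: np.ndarray
    dosage: np.ndarray
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None
    polarized: bool = False

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def validate(self) -> None:
        if self.dosage.shape != (self.n_samples, self.n_sites):
            raise FormatError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{self.n_samples} samples x {self.n_sites} sites"
            )
        for arr, name in ((self.chrom, "chrom"), (self.ref, "ref"),
                          (self.alt, "alt"), (self.ancestral, "ancestral")):
            if len(arr) != self.n_sites:
                raise FormatError(f"{name} length != n_sites")
        if np.any((self.ref == self.alt) & (self.ref != "N")):
            raise FormatError("ref == alt at some site")
        ok = (self.ancestral == self.ref) | (self.ancestral == self.alt) \
            | (self.ancestral == "N")
        if not np.all(ok):
            raise FormatError("ancestral allele matches neither ref nor alt")
        # positions strictly increasing within each chromosome
        for c in dict.fromkeys(self.chrom.tolist()):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and np.any(np.diff(p) <= 0):
                raise FormatError(f"positions not strictly increasing on {c}")
        valid = (self.dosage >= MISSING) & (self.dosage <= 2)
        if not np.all(valid):
            raise FormatError("dosages outside {missing,0,1,2}")

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset (or reorder) sites by integer or boolean index."""
        index = np.asarray(index)
        return replace(
            self,
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            ancestral=self.ancestral[index],
            dosage=self.dosage[:, index],
            gq=None if self.gq is None else self.gq[:, index],
            dp=None if self.dp is None else self.dp[:, index],
        )

    def take_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in index],
            dosage=self.dosage[index],
            gq=None if self.gq is None else self.gq[index],
            dp=None if self.dp is None else self.dp[index],
        )

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt_count, called_allele_count) over non-missing calls."""
        called = self.dosage != MISSING
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        return alt, 2 * called.sum(axis=0)

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            sample_ids=list(self.sample_ids),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            ancestral=self.ancestral.copy(),
            dosage=self.dosage.copy(),
            gq=None if self.gq is None else self.gq.copy(),
            dp=None if self.dp is None else self.dp.copy(),
        )


@dataclass
class PopulationMap:
    """sample_id -> population label."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if any(not v for v in self.mapping.values()):
            raise FormatError("empty population label")

    def populations(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def sample_index(self, matrix: GenotypeMatrix) -> dict[str, np.ndarray]:
        """Population -> integer indices into matrix.sample_ids."""
        missing = [s for s in matrix.sample_ids if s not in self.mapping]
        if missing:
            raise FormatError(f"samples not in population map: {missing}")
        out: dict[str, list[int]] = {}
        for i, s in enumerate(matrix.sample_ids):
            out.setdefault(self.mapping[s], []).append(i)
        return {k: np.array(v) for k, v in out.items()}


VALID_CLASSES = ("synonymous", "nonsynonymous", "other")


@dataclass
class AnnotationTable:
    """Per-site functional annotation aligned with a GenotypeMatrix.

    ``score`` is a deleteriousness score in [0, 1] (SIFT convention:
    smaller is more deleterious); NaN when absent.  ``near_gene`` flags
    sites within 5 kb of an annotated gene region.
    """

    chrom: np.ndarray
    pos: np.ndarray
    klass: np.ndarray       # str array over VALID_CLASSES
    score: np.ndarray       # float, NaN = absent
    near_gene: np.ndarray   # bool

    def __post_init__(self) -> None:
        bad = set(np.unique(self.klass)) - set(VALID_CLASSES)
        if bad:
            raise FormatError(f"unknown annotation class labels: {sorted(bad)}")
        with_score = ~np.isnan(self.score)
        if np.any(with_score & ((self.score < 0) | (self.score > 1))):
            raise FormatError("scores must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.pos)


@dataclass
class DemographicModel:
    """Piecewise-constant diploid population-size history.

    Epochs are ordered most recent first; each is ``(duration in
    generations, diploid Ne)`` and exactly the last duration is
    ``inf``.  ``mu`` is the per-site per-generation mutation rate and
    ``generation_time_years`` converts generations to years.
    """

    epochs: list[tuple[float, float]]
    mu: float = 1.2e-7
    generation_time_years: float = 30.0

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ParameterError("at least one epoch required")
        durations = [d for d, _ in self.epochs]
        if not np.isinf(durations[-1]) or any(np.isinf(d) for d in durations[:-1]):
            raise ParameterError("exactly the terminal epoch must be infinite")
        if any(n < 2 for _, n in self.epochs):
            raise ParameterError("all Ne must be >= 2")
        if not self.mu > 0:
            raise ParameterError("mu must be positive")
        if not self.generation_time_years > 0:
            raise ParameterError("generation time must be positive")

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated genotype data."""

    ancestral: np.ndarray                    # per-site true ancestral base
    population: list[str] = field(default_factory=list)   # per sample
    admixture: np.ndarray | None = None      # samples x K, rows sum to 1
    selection_s: np.ndarray | None = None    # per-site selection coefficient
    site_class: np.ndarray | None = None     # per-site class label
    derived_freq: np.ndarray | None = None   # per-site true derived frequency

    def __post_init__(self) -> None:
        if self.admixture is not None:
            if not np.allclose(self.admixture.sum(axis=1), 1.0):
                raise ParameterError("admixture rows must sum to 1")
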