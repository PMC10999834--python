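"""Runs of homozygosity and the genomic inbreeding coefficient FROH.

ROH calling uses a two-state HMM (autozygous / non-autozygous) over the
per-site observation sequence {hom, het, missing} of one individual.
Heterozygotes inside autozygous tracts are allowed at a small genotype
error rate; in non-autozygous background the heterozygote emission
equals the individual's per-chromosome empirical heterozygosity.  State
switches are priced per base pair so sparse regions do not fragment
calls.  The Viterbi path is decoded exactly and autozygous stretches
passing length and site-count minima become segments, with boundaries
at the outermost sites of the stretch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, ParameterError

logger = __import__("logging").getLogger("consgen")


@dataclass
class HMMConfig:
    """ROH HMM parameters (defaults documented in the methods note)."""

    het_in_roh: float = 0.005         # genotype-error allowance
    switch_per_bp: float = 1e-8       # transition price per bp
    max_switch: float = 0.49          # cap on per-step switch probability
    min_length: int = 100_000         # bp
    min_sites: int = 25
    # floor for the empirical background het rate; kept above het_in_roh
    # so the two states stay identifiable on hom-only chromosomes
    min_het_background: float = 0.02


@dataclass
class ROHSegment:
    sample: str
    chrom: str
    start: int    # 0-based half-open
    end: int
    n_sites: int
    n_het_inside: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _emissions(obs: np.ndarray, eps: float, het_rate: float) -> np.ndarray:
    """(n_sites, 2) emission probabilities; state 0 = autozygous."""
    e = np.ones((len(obs), 2))
    hom = obs == 0
    het = obs == 1
    e[hom, 0] = 1 - eps
    e[het, 0] = eps
    e[hom, 1] = 1 - het_rate
    e[het, 1] = het_rate
    # missing (obs == 2) stays uninformative: 1 in both states
    return e


def viterbi_two_state(obs: np.ndarray, gaps_bp: np.ndarray,
                      eps: float, het_rate: float,
                      switch_per_bp: float, max_switch: float) -> np.ndarray:
    """Exact 2-state Viterbi over observations {0 hom, 1 het, 2 missing}.

    ``gaps_bp[i]`` is the distance from site i-1 to site i (len-1
    entries).  Uniform initial state probabilities.  Returns the state
    path (0 = autozygous).
    """
    e = np.log(_emissions(obs, eps, het_rate))
    n = len(obs)
    switch = np.minimum(switch_per_bp * gaps_bp, max_switch)
    stay = 1.0 - switch
    delta = np.log(0.5) + e[0]
    back = np.zeros((n, 2), dtype=np.int8)
    log_stay = np.log(stay)
    log_switch = np.log(switch)
    for i in range(1, n):
        ls, lw = log_stay[i - 1], log_switch[i - 1]
        # candidate scores arriving at state s from previous states (0, 1)
        c0 = (delta[0] + ls, delta[1] + lw)
        c1 = (delta[0] + lw, delta[1] + ls)
        back[i, 0] = c0[1] > c0[0]
        back[i, 1] = c1[1] > c1[0]
        delta = np.array([max(c0) + e[i, 0], max(c1) + e[i, 1]])
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def detect_roh(matrix: GenotypeMatrix, sample: str,
               config: HMMConfig | None = None) -> list[ROHSegment]:
    """Call ROH segments for one sample across all chromosomes."""
    if config is None:
        config = HMMConfig()
    try:
        si = matrix.sample_ids.index(sample)
    except ValueError as exc:
        raise ParameterError(f"unknown sample {sample!r}") from exc
    segments: list[ROHSegment] = []
    for c in dict.fromkeys(matrix.chrom.tolist()):
        idx = np.where(matrix.chrom == c)[0]
        if len(idx) < config.min_sites:
            logger.info("detect_roh: chromosome %s has < %d sites, skipped",
                        c, config.min_sites)
            continue
        pos = matrix.pos[idx]
        dos = matrix.dosage[si, idx]
        obs = np.where(dos == MISSING, 2, np.where(dos == 1, 1, 0))
        called = obs != 2
        if not called.any():
            logger.info("detect_roh: no called genotypes on %s, skipped", c)
            continue
        het_rate = float(np.clip((obs[called] == 1).mean(),
                                 config.min_het_background, 1 - 1e-9))
        path = viterbi_two_state(
            obs, np.diff(pos).astype(float), config.het_in_roh, het_rate,
            config.switch_per_bp, config.max_switch)
        in_roh = path == 0
        boundaries = np.flatnonzero(np.diff(in_roh.astype(int)))
        starts = [0] + (boundaries + 1).tolist()
        for a, b in zip(starts, boundaries.tolist() + [len(in_roh) - 1]):
            if not in_roh[a]:
                continue
            seg_sites = np.arange(a, b + 1)
            start_bp = int(pos[a])
            end_bp = int(pos[b]) + 1
            seg = ROHSegment(
                sample=sample, chrom=c, start=start_bp, end=end_bp,
                n_sites=len(seg_sites),
                n_het_inside=int(np.sum(obs[seg_sites] == 1)))
            if seg.length >= config.min_length and seg.n_sites >= config.min_sites:
                segments.append(seg)
    return segments


@dataclass
class FrohResult:
    sample: str
    total_roh_bp: int
    genome_length: int
    froh: float


def froh(segments: list[ROHSegment], genome_length: int,
         sample: str | None = None) -> FrohResult:
    """FROH = merged total ROH length / genome length."""
    if genome_length <= 0:
        raise ParameterError("genome_length must be positive")
    if sample is None:
        sample = segments[0].sample if segments else ""
    from .filtering import merge_intervals
    merged = merge_intervals([(s.chrom, s.start, s.end) for s in segments
                              if s.sample == sample or sample == ""])
    total = sum(e - s for _, s, e in merged)
    if total > genome_length:
        raise ParameterError("total ROH length exceeds genome length")
    return FrohResult(sample=sample, total_roh_bp=total,
                      genome_length=genome_length,
                      froh=total / genome_length)


def froh_table(matrix: GenotypeMatrix, genome_length: int,
               config: HMMConfig | None = None,
               popmap=None) -> pd.DataFrame:
    rows = []
    for s in matrix.sample_ids:
        segs = detect_roh(matrix, s, config)
        res = froh(segs, genome_length, sample=s)
        rows.append((s, len(segs), res.total_roh_bp, res.froh))
    df = pd.DataFrame(rows, columns=["sample", "n_segments",
                                     "total_roh_bp", "froh"])
    if popmap is not None:
        df["population"] = [popmap.mapping[s] for s in matrix.sample_ids]
    return df


def segments_to_bed(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.chrom, s.start, s.end, s.sample, s.n_sites, s.n_het_inside)
         for s in segments],
        columns=["chrom", "start", "end", "sample", "n_sites", "n_het"])
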