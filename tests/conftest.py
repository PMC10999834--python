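"""Shared fixtures: tiny hand-written VCF text, toy matrices, popmaps."""

from __future__ import annotations

import io as _io

import numpy as np
import pytest

from consgen.core import GenotypeMatrix, PopulationMap


def make_matrix(dosage, pos=None, chrom=None, ref=None, alt=None,
                ancestral=None, gq=None, dp=None, sample_ids=None,
                polarized=False) -> GenotypeMatrix:
    """Compact GenotypeMatrix builder for toy tests."""
    dosage = np.asarray(dosage, dtype=np.int16)
    n_samples, n_sites = dosage.shape
    if pos is None:
        pos = np.arange(n_sites) * 100
    if chrom is None:
        chrom = ["chr1"] * n_sites
    m = GenotypeMatrix(
        sample_ids=(sample_ids or [f"s{i+1}" for i in range(n_samples)]),
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref if ref is not None else ["A"] * n_sites,
                       dtype=object),
        alt=np.asarray(alt if alt is not None else ["T"] * n_sites,
                       dtype=object),
        ancestral=np.asarray(ancestral if ancestral is not None
                             else ["A"] * n_sites, dtype=object),
        dosage=dosage,
        gq=None if gq is None else np.asarray(gq, dtype=np.int32),
        dp=None if dp is None else np.asarray(dp, dtype=np.int32),
        polarized=polarized,
    )
    m.validate()
    return m


FIVE_LINE_VCF = """\
##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##contig=<ID=chr1,length=10000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr1\t101\t.\tA\tG\t.\tPASS\tAA=G\tGT:GQ:DP\t0/0:50:20\t0/1:44:18\t1/1:60:22
chr1\t205\t.\tC\tT\t.\tPASS\tAA=C\tGT:GQ:DP\t0/1:33:11\t./.:.:.\t0/0:21:9
chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT:GQ:DP\t1/1:19:4\t0/0:25:12\t0/1:48:15
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    p = tmp_path / "tiny.vcf"
    p.write_text(FIVE_LINE_VCF)
    return p


@pytest.fixture
def popmap5():
    return PopulationMap({
        **{f"DLS_{i}": "DLS" for i in range(1, 7)},
        **{f"FD_{i}": "FD" for i in range(1, 7)},
        "MAD_1": "MAD",
        **{f"MC_{i}": "MC" for i in range(1, 5)},
        **{f"XZQ_{i}": "XZQ" for i in range(1, 5)},
    })


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
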