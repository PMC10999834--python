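"""Readers and writers for the formats the pipeline touches.

VCF is read with :mod:`cyvcf2` and written as plain VCF 4.2 text (the
pipeline only consumes CHROM/POS/REF/ALT, per-genotype GT/GQ/DP and
INFO/AA).  Population maps and annotation tables are TSV; trees are
newick parsed with Bio.Phylo.  All positions are converted to the
internal 0-based convention on read and back to 1-based on write.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Phylo
from cyvcf2 import VCF

from .core import (MISSING, AnnotationTable, FormatError, GenotypeMatrix,
                   PopulationMap, VALID_CLASSES)

logger = logging.getLogger("consgen")


def read_vcf(path: str | Path, region: str | None = None,
             strict: bool = True) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    With ``strict=True`` (default) only biallelic SNP records are kept;
    otherwise every record is loaded.  ``./.`` genotypes become missing
    dosages and INFO/AA, when present and matching REF or ALT, is
    stored as the ancestral allele (otherwise ``'N'``).
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises plain exceptions on bad headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    chroms, poss, refs, alts, ancs = [], [], [], [], []
    dosages, gqs, dps = [], [], []
    any_gq = any_dp = False
    iterator = vcf(region) if region else vcf
    for var in iterator:
        is_biallelic_snp = (len(var.ALT) == 1 and len(var.REF) == 1
                            and len(var.ALT[0]) == 1
                            and var.REF != var.ALT[0])
        if strict and not is_biallelic_snp:
            continue
        if len(var.genotypes) != len(samples):
            raise FormatError(
                f"record {var.CHROM}:{var.POS} has {len(var.genotypes)} "
                f"genotypes for {len(samples)} header samples")
        # non-strict mode keeps multi-allelic records tagged by a
        # comma-joined ALT so the biallelic site filter can drop them
        alt = ",".join(var.ALT) if var.ALT else "N"
        chroms.append(var.CHROM)
        poss.append(var.POS - 1)
        refs.append(var.REF)
        alts.append(alt)
        aa = var.INFO.get("AA")
        ancs.append(aa if aa in (var.REF, alt) else "N")
        row = np.full(len(samples), MISSING, dtype=np.int16)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a >= 0 and b >= 0:
                row[i] = int(a > 0) + int(b > 0)
        dosages.append(row)
        gq = var.format("GQ")
        if gq is not None:
            any_gq = True
            gqs.append(np.where(gq[:, 0] < 0, MISSING, gq[:, 0]))
        else:
            gqs.append(np.full(len(samples), MISSING))
        dp = var.format("DP")
        if dp is not None:
            any_dp = True
            dps.append(np.where(dp[:, 0] < 0, MISSING, dp[:, 0]))
        else:
            dps.append(np.full(len(samples), MISSING))
    n_sites = len(poss)
    mat = GenotypeMatrix(
        sample_ids=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        ancestral=np.array(ancs, dtype=object),
        dosage=(np.stack(dosages, axis=1) if n_sites
                else np.zeros((len(samples), 0), dtype=np.int16)),
        gq=np.stack(gqs, axis=1).astype(np.int32) if any_gq and n_sites else None,
        dp=np.stack(dps, axis=1).astype(np.int32) if any_dp and n_sites else None,
    )
    mat.validate()
    return mat


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""

_GT_STRINGS = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> Path:
    """Write a matrix as VCF 4.2; inverse of :func:`read_vcf`.

    Sites with ancestral ``'N'`` carry no AA key.  GQ/DP FORMAT fields
    are emitted only when present on the matrix.
    """
    matrix.validate()
    path = Path(path)
    fmt = ["GT"]
    if matrix.gq is not None:
        fmt.append("GQ")
    if matrix.dp is not None:
        fmt.append("DP")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in dict.fromkeys(matrix.chrom.tolist()):
            length = int(matrix.pos[matrix.chrom == c].max()) + 2
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        for j in range(matrix.n_sites):
            info = (f"AA={matrix.ancestral[j]}"
                    if matrix.ancestral[j] != "N" else ".")
            cells = []
            for i in range(matrix.n_samples):
                parts = [_GT_STRINGS[int(matrix.dosage[i, j])]]
                if matrix.gq is not None:
                    v = int(matrix.gq[i, j])
                    parts.append("." if v == MISSING else str(v))
                if matrix.dp is not None:
                    v = int(matrix.dp[i, j])
                    parts.append("." if v == MISSING else str(v))
                cells.append(":".join(parts))
            fh.write("\t".join([
                str(matrix.chrom[j]), str(int(matrix.pos[j]) + 1), ".",
                str(matrix.ref[j]), str(matrix.alt[j]), ".", "PASS",
                info, ":".join(fmt), *cells]) + "\n")
    return path


def read_popmap(path: str | Path) -> PopulationMap:
    """Two-column TSV ``sample_id<TAB>population`` -> PopulationMap."""
    mapping: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{ln}: expected 2 columns")
        sample, pop = parts
        if sample in mapping:
            raise FormatError(f"{path}:{ln}: duplicate sample id {sample!r}")
        mapping[sample] = pop
    return PopulationMap(mapping)


def read_annotations(path: str | Path) -> AnnotationTable:
    """TSV with columns chrom, pos (1-based), class, score, near_gene."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     na_values=["."], keep_default_na=True)
    required = {"chrom", "pos", "class", "score", "near_gene"}
    if not required <= set(df.columns):
        raise FormatError(f"annotation TSV must have columns {sorted(required)}")
    bad = set(df["class"].unique()) - set(VALID_CLASSES)
    if bad:
        raise FormatError(f"unknown class labels: {sorted(bad)}")
    return AnnotationTable(
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64) - 1,
        klass=df["class"].to_numpy(dtype=object),
        score=df["score"].to_numpy(dtype=float),
        near_gene=df["near_gene"].astype(bool).to_numpy(),
    )


def write_annotations(ann: AnnotationTable, path: str | Path) -> Path:
    df = pd.DataFrame({
        "chrom": ann.chrom, "pos": ann.pos + 1, "class": ann.klass,
        "score": ann.score, "near_gene": ann.near_gene.astype(int),
    })
    df.to_csv(path, sep="\t", index=False, na_rep=".")
    return Path(path)


def read_tree(path: str | Path):
    """Parse a rooted newick tree; rejects negative branch lengths."""
    tree = Phylo.read(str(path), "newick")
    for clade in tree.find_clades():
        if clade.branch_length is not None and clade.branch_length < 0:
            raise FormatError("negative branch length in tree")
    names = [c.name for c in tree.get_terminals()]
    if len(names) != len(set(names)):
        raise FormatError("duplicate leaf labels in tree")
    return tree


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """BED (0-based half-open) -> list of (chrom, start, end)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        c, s, e = line.split("\t")[:3]
        out.append((c, int(s), int(e)))
    return out
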