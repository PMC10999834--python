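#!/usr/bin/env python
"""Derived deleterious-mutation load per individual and population.

Classifies annotated sites by the SIFT convention (nonsynonymous with
score < 0.05 = deleterious), counts HoDA/HeDA per individual on the
polarized dosages, partitions deleterious derived alleles into the
5-population sharing (Venn) regions, and summarizes the DAF spectrum.

Writes results/load_per_sample.tsv, load_sharing.tsv, load_summary.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from consgen import io, load

BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    mat = io.read_vcf(BASE / "polarized.vcf")
    mat.polarized = True
    popmap = io.read_popmap(BASE / "cohort" / "popmap.tsv")
    ann = io.read_annotations(BASE / "cohort" / "annotations.tsv")
    idx = pd.MultiIndex.from_arrays([ann.chrom, ann.pos])
    order = pd.Series(np.arange(ann.n_sites), index=idx) \
        .loc[pd.MultiIndex.from_arrays([mat.chrom, mat.pos])].to_numpy()
    classes = load.classify_sites(ann)[order]

    summary = load.load_summary(mat, classes, popmap)
    summary.per_sample.to_csv(BASE / "load_per_sample.tsv", sep="\t",
                              index=False)
    print(f"deleterious {summary.n_deleterious}, "
          f"synonymous {summary.n_synonymous}, "
          f"tolerated {summary.n_tolerated} sites")
    print(f"mean HoDA {summary.per_sample['HoDA'].mean():.1f}, "
          f"mean HeDA {summary.per_sample['HeDA'].mean():.1f}")
    print(f"{100 * summary.frac_daf_below:.2f}% of deleterious sites have "
          f"DAF < {summary.daf_threshold}")
    print(f"{100 * summary.frac_homozygous:.1f}% "
          f"({summary.n_homozygous_sites}/{summary.n_deleterious}) carried "
          f"homozygous by >= 1 individual")

    pres = load.population_presence(mat, classes, popmap, mode="any")
    part = load.sharing_partition(pres)
    rows = [("|".join(sorted(k)), v)
            for k, v in sorted(part.region_counts.items(),
                               key=lambda kv: -kv[1])]
    pd.DataFrame(rows, columns=["populations", "alleles"]) \
        .to_csv(BASE / "load_sharing.tsv", sep="\t", index=False)
    shared_all = part.shared_by_all(popmap.populations())
    print(f"{part.n_alleles} deleterious derived alleles present; "
          f"{shared_all} shared by all 5 populations")
    priv = {p: round(f, 3) for p, f in part.private_fraction.items()}
    print(f"private fractions: {priv}")

    pd.DataFrame([{
        "n_deleterious": summary.n_deleterious,
        "n_synonymous": summary.n_synonymous,
        "n_tolerated": summary.n_tolerated,
        "frac_daf_below_0.05": summary.frac_daf_below,
        "frac_homozygous": summary.frac_homozygous,
    }]).to_csv(BASE / "load_summary.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
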