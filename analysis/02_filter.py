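#!/usr/bin/env python
"""Apply the dataset-style filter chain to the synthetic cohort.

Stages mirror the resequencing workflow: genotype masking (GQ < 20 or
DP < 5 -> missing; the synthetic VCF carries no GQ/DP so the stage
logs and passes through), then the site filters in two steps matching
the dataset lineage —

  dataset 2: biallelic SNPs with missing rate <= 20%
  dataset 3: dataset 2 with MAF >= 5%
  dataset 4: dataset 3 LD-pruned (50-site window, 10-site step, r^2 0.2)

The summed-depth window is skipped without DP.  Writes
results/dataset2.vcf, dataset3.vcf, dataset4.vcf, filter_report.tsv.
"""

from pathlib import Path

from consgen import filtering, io

BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    mat = io.read_vcf(BASE / "cohort" / "cohort.vcf")
    masked = filtering.mask_genotypes(mat)
    ds2, report = filtering.filter_sites(masked, total_depth_range=None,
                                         min_maf=0.0)
    ds3, report = filtering.filter_sites(ds2, total_depth_range=None,
                                         report=report)
    ds4 = filtering.ld_prune(ds3)
    io.write_vcf(ds2, BASE / "dataset2.vcf")
    io.write_vcf(ds3, BASE / "dataset3.vcf")
    io.write_vcf(ds4, BASE / "dataset4.vcf")
    df = report.to_frame()
    df.to_csv(BASE / "filter_report.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"{mat.n_sites} sites in; dataset2 {ds2.n_sites}, "
          f"dataset3 {ds3.n_sites}, dataset4 {ds4.n_sites}")


if __name__ == "__main__":
    main()
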