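"""A fully hand-enumerated 20-site toy VCF exercising the filter chain.

Every rule of the dataset-1..4 chain (genotype masking, summed-depth
bounds, biallelic/SNP, missingness, MAF, LD pruning) is triggered by at
least one site, with boundary cases on both sides.  The expected
surviving sets are derivable by hand from the printed dosage table and
are frozen in EXPECTED_* below.
"""

from __future__ import annotations

N_TOY_SAMPLES = 21

# surviving-site dosage patterns (21 samples), chosen so every
# off-pair r^2 < 0.2 except the planted duplicate 16/17
_P = {
    1: [1, 0, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 1, 0, 0, 0, 0, 1, 1, 1, 0],
    3: [0, 0, 1, 1, 0, 1, 0, 1, 0, 0, 1, 1, 1, 1, 0, 0, 1, 1, 0, 0, 0],
    6: [0, 0, 0, 1, 1, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 1, 1, 0, 1, 0],
    13: [1, 0, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    14: [0, 0, 0, 0, 1, 0, 0, 1, 0, 1, 0, 1, 0, 0, 1, 0, 1, 0, 0, 0, 0],
    16: [1, 0, 0, 1, 1, 0, 1, 1, 1, 0, 1, 0, 1, 0, 0, 0, 1, 1, 0, 0, 0],
    18: [0, 0, 0, 1, 0, 0, 1, 0, 1, 1, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0],
    19: [0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 1, 0, 1, 0, 1, 1, 1, 1, 1, 0],
    20: [0, 0, 0, 0, 1, 0, 0, 0, 1, 0, 1, 0, 0, 1, 0, 0, 0, 1, 0, 2, 0],
}

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def _toy_vcf_text():
    """20-site, 21-sample VCF exercising every dataset-1..4 rule."""
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">',
             '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">',
             "##contig=<ID=chr1,length=25000>",
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(f"s{i+1}" for i in range(N_TOY_SAMPLES))]

    def record(pos, ref, alt, cells):
        return f"chr1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:GQ:DP\t" \
            + "\t".join(cells)

    def cells_from(dosages, gq=None, dp=None, missing=()):
        out = []
        for i, d in enumerate(dosages):
            if i in missing:
                out.append("./.:.:.")
                continue
            g = gq[i] if gq else 50
            p = dp[i] if dp else 10
            out.append(f"{_GT[d]}:{g}:{p}")
        return out

    rows = []
    # 1: clean polymorphic site, survives everything
    rows.append(record(1_000, "A", "T", cells_from(_P[1])))
    # 2: five GQ=19 cells get masked -> missing rate 5/21 > 20%
    gq = [19] * 5 + [50] * 16
    dos2 = [1] * 13 + [0] * 8
    rows.append(record(2_000, "A", "T", cells_from(dos2, gq=gq)))
    # 3: three DP=4 cells masked (3/21 = 14.3% missing, site kept)
    dp = [10] * 18 + [4] * 3
    rows.append(record(3_000, "A", "T", cells_from(_P[3], dp=dp)))
    # 4: DP=4 everywhere; summed depth 84 < 100 -> depth-removed
    rows.append(record(4_000, "A", "T",
                       cells_from([1] * 21, dp=[4] * 21)))
    # 5: DP=30 everywhere; summed depth 630 > 600 -> depth-removed
    rows.append(record(5_000, "A", "T",
                       cells_from([1] * 10 + [0] * 11, dp=[30] * 21)))
    # 6: summed depth exactly 600 (12x29 + 9x28) -> retained
    rows.append(record(6_000, "A", "T",
                       cells_from(_P[6], dp=[29] * 12 + [28] * 9)))
    # 7: summed depth exactly 601 (13x29 + 8x28) -> removed
    rows.append(record(7_000, "A", "T",
                       cells_from([1] * 7 + [0] * 14,
                                  dp=[29] * 13 + [28] * 8)))
    # 8: multi-allelic -> removed by the biallelic/SNP rule
    cells = ["0/1:50:10"] * 10 + ["0/2:50:10"] * 5 + ["0/0:50:10"] * 6
    rows.append(record(8_000, "A", "T,G", cells))
    # 9: indel REF -> removed by the biallelic/SNP rule
    rows.append(record(9_000, "AT", "A",
                       cells_from([1] * 8 + [0] * 13)))
    # 10: monomorphic reference -> MAF 0 -> removed
    rows.append(record(10_000, "A", "T", cells_from([0] * 21)))
    # 11: singleton 1/42 = 0.024 < 0.05 -> removed
    rows.append(record(11_000, "A", "T", cells_from([1] + [0] * 20)))
    # 12: homozygous doubleton 2/42 = 0.048 < 0.05 -> removed
    rows.append(record(12_000, "A", "T", cells_from([2] + [0] * 20)))
    # 13: tripleton 3/42 = 0.071 >= 0.05 -> kept
    rows.append(record(13_000, "A", "T", cells_from(_P[13])))
    # 14: four ./. cells = 19.0% missing -> kept
    rows.append(record(14_000, "A", "T",
                       cells_from(_P[14], missing=(17, 18, 19, 20))))
    # 15: five ./. cells = 23.8% missing -> removed
    rows.append(record(15_000, "A", "T",
                       cells_from([1] * 9 + [0] * 12,
                                  missing=(16, 17, 18, 19, 20))))
    # 16/17: identical dosage vectors, r^2 = 1 -> 17 pruned
    rows.append(record(16_000, "A", "T", cells_from(_P[16])))
    rows.append(record(17_000, "A", "T", cells_from(_P[16])))
    # 18: independent common site -> survives
    rows.append(record(18_000, "A", "T", cells_from(_P[18])))
    # 19: GQ exactly 20 everywhere -> boundary retained
    rows.append(record(19_000, "A", "T",
                       cells_from(_P[19], gq=[20] * 21)))
    # 20: DP exactly 5 everywhere (sum 105) -> boundary retained
    rows.append(record(20_000, "A", "T",
                       cells_from(_P[20], dp=[5] * 21)))
    return "\n".join(lines + rows) + "\n"



# hand-enumerated expectations (site numbers = POS / 1000)
EXPECTED_AFTER_FILTERS = [1, 3, 6, 13, 14, 16, 17, 18, 19, 20]
EXPECTED_AFTER_PRUNING = [1, 3, 6, 13, 14, 16, 18, 19, 20]
EXPECTED_STAGE_REMOVALS = {
    "total_depth": 3,      # sites 4, 5, 7
    "biallelic_snp": 2,    # sites 8, 9
    "missingness": 2,      # sites 2, 15
    "maf": 3,              # sites 10, 11, 12
}

toy_vcf_text = _toy_vcf_text
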