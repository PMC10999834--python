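#!/usr/bin/env python
"""Genome-wide diversity of the synthetic cohort.

Computes 20-kb/10-kb sliding-window theta_W, theta_pi, Tajima's D and
Fu & Li's D, per-individual heterozygosity (over all candidate sites as
the callable denominator), pairwise Hudson FST between the 5
subpopulations, and LD decay.

Writes results/window_stats.tsv, heterozygosity.tsv, fst.tsv,
ld_decay.tsv and a LD-decay plot.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from consgen import diversity, io

BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    mat = io.read_vcf(BASE / "dataset3.vcf")
    popmap = io.read_popmap(BASE / "cohort" / "popmap.tsv")

    ws = diversity.window_stats(mat)
    ws.to_csv(BASE / "window_stats.tsv", sep="\t", index=False)
    print(f"windows: {len(ws)}; genome-wide means "
          f"theta_w={ws['theta_w'].mean():.3e} "
          f"theta_pi={ws['theta_pi'].mean():.3e} "
          f"Tajima's D={ws['tajimas_d'].mean():.3f}")

    full = io.read_vcf(BASE / "cohort" / "cohort.vcf")
    het = diversity.individual_heterozygosity(full, full.n_sites, popmap)
    het.to_csv(BASE / "heterozygosity.tsv", sep="\t", index=False)
    print("mean per-candidate-site heterozygosity: "
          f"{het['het_rate'].mean():.4f} "
          f"(range {het['het_rate'].min():.4f}-{het['het_rate'].max():.4f})")

    fst = diversity.pairwise_fst(mat, popmap)
    fdf = pd.DataFrame([(r.pop1, r.pop2, r.fst, r.estimator, r.n_sites)
                        for r in fst],
                       columns=["pop1", "pop2", "fst", "estimator",
                                "n_sites"])
    fdf.to_csv(BASE / "fst.tsv", sep="\t", index=False)
    print(f"mean pairwise Hudson FST: {fdf['fst'].mean():.3f}")

    ld = diversity.ld_decay(mat, max_dist=1_000_000, bin_width=50_000)
    ld.to_csv(BASE / "ld_decay.tsv", sep="\t", index=False)
    ok = ld.dropna()
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot((ok["dist_low"] + ok["dist_high"]) / 2e3, ok["mean_r2"],
            marker="o", ms=3)
    ax.set_xlabel("distance (kb)")
    ax.set_ylabel("mean $r^2$")
    fig.tight_layout()
    fig.savefig(BASE / "ld_decay.png", dpi=120)
    print(f"LD decay: first-bin r2 {ok['mean_r2'].iloc[0]:.3f}, "
          f"last-bin r2 {ok['mean_r2'].iloc[-1]:.3f}")


if __name__ == "__main__":
    main()
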