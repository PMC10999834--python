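#!/usr/bin/env python
"""Generate the synthetic study cohort with known truth.

Mirrors the resequencing design this pipeline targets: 21 diploid
trees from 5 relict subpopulations (DLS 6, FD 6, MAD 1, MC 4, XZQ 4),
weak differentiation, a small deleterious fraction among nonsynonymous
sites, a genic annotation layer, and an outgroup alignment evolved from
the true ancestral states on a fixed 4-taxon tree.  The genome is
scaled to 10 x 1 Mb chromosomes so downstream stages run in seconds.

Writes results/cohort/: cohort.vcf, popmap.tsv, annotations.tsv,
genes.bed, outgroup.nwk, outgroup_states.tsv, truth tables.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from consgen import io, simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 2024
CHROM_MAP = [(f"chr{i+1}", 1_000_000) for i in range(10)]
POP_SIZES = {"DLS": 6, "FD": 6, "MAD": 1, "MC": 4, "XZQ": 4}
NEWICK = "((ingroup:0.02,M_rel1:0.06):0.04,(M_rel2:0.08,L_out:0.15):0.05);"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    demes = list(POP_SIZES)
    # weak migration keeps FST low, matching the observed K=1 pattern
    D = len(demes)
    mig = np.full((D, D), 0.01 / (D - 1))
    np.fill_diagonal(mig, 0.0)
    selection = [
        {"name": "neutral", "fraction": 0.90, "s": 0.0, "h": 0.5},
        {"name": "deleterious", "fraction": 0.10, "s": 0.05, "h": 0.1},
    ]
    mat, truth = simulate.simulate_wright_fisher_forward(
        N_diploid=[60] * D, L_sites=6_000, n_generations=80,
        sample_sizes_per_pop=list(POP_SIZES.values()), seed=SEED,
        chromosome_map=CHROM_MAP, recomb_per_bp=1e-8,
        selection_config=selection, migration_matrix=mig,
        pop_names=demes)
    io.write_vcf(mat, OUT / "cohort.vcf")
    with open(OUT / "popmap.tsv", "w") as fh:
        for s, p in zip(mat.sample_ids, truth.population):
            fh.write(f"{s}\t{p}\n")

    genes = simulate.simulate_gene_intervals(CHROM_MAP, seed=SEED + 1)
    with open(OUT / "genes.bed", "w") as fh:
        for c, s, e in genes:
            fh.write(f"{c}\t{s}\t{e}\n")
    ann = simulate.attach_annotations(
        mat, {"synonymous": 0.6, "nonsynonymous": 0.4},
        {"deleterious_mass": 0.3}, seed=SEED + 2, gene_intervals=genes)
    io.write_annotations(ann, OUT / "annotations.tsv")

    (OUT / "outgroup.nwk").write_text(NEWICK + "\n")
    tree = io.read_tree(OUT / "outgroup.nwk")
    states = simulate.simulate_outgroup_alignment(tree, truth.ancestral,
                                                  seed=SEED + 3)
    pd.DataFrame({"chrom": mat.chrom, "pos": mat.pos + 1,
                  **{k: v for k, v in states.items()}}) \
        .to_csv(OUT / "outgroup_states.tsv", sep="\t", index=False)
    pd.DataFrame({"chrom": mat.chrom, "pos": mat.pos + 1,
                  "ancestral": truth.ancestral,
                  "class": truth.site_class,
                  "s": truth.selection_s,
                  "derived_freq": truth.derived_freq}) \
        .to_csv(OUT / "truth_sites.tsv", sep="\t", index=False)

    het = (mat.dosage == 1).mean(axis=1)
    seg = ((mat.dosage.sum(axis=0) > 0)
           & (mat.dosage.sum(axis=0) < 2 * mat.n_samples)).sum()
    print(f"cohort: {mat.n_samples} samples, {mat.n_sites} candidate sites, "
          f"{seg} segregating")
    print(f"mean per-SNP heterozygous fraction: {het.mean():.3f}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
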