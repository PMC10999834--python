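# consgen

A conservation-genomics analysis pipeline for species reduced to a
handful of relict populations, built around the resequencing design
used for *Magnolia sinica* (21 diploid trees from 5 subpopulations):
variant filtering, genome-wide diversity, ancestral-allele
polarization, site-frequency-spectrum demographic inference,
runs-of-homozygosity inbreeding, derived deleterious-mutation load,
LD-based contemporary Ne, and admixture-style population structure.

The package is written for analysts who need the *whole* chain to be
reproducible and testable without the original reads: a first-class
synthetic-data module generates genotype cohorts with known truth
(demography, structure, selection, ancestral states), and every
downstream estimator is validated against that truth or against
brute-force oracles.

## What it computes

* **Filter chain** — genotype masking (GQ < 20 or DP < 5 → missing),
  site filters in the order summed-depth ∈ [100, 600] →
  biallelic SNP → missing rate ≤ 20% → MAF ≥ 0.05, and greedy
  `50 10 0.2` LD pruning on genotype r².
* **Diversity** — sliding-window (20 kb / 10 kb) Watterson's
  θ̂_W = S/(a_n L), nucleotide diversity θ̂_π = Σ 2d(n−d)/(n(n−1))/L,
  Tajima's D and Fu & Li's D with the published variance constants;
  individual heterozygosity; pairwise Hudson FST as a ratio of
  averages; LD decay in distance bins.
* **Polarization** — Felsenstein pruning + marginal posteriors under
  JC69 on a fixed rooted tree; ancestral base called where the
  posterior ≥ 0.95 (ties → N); dosages recoded to derived-allele
  counts with per-site DAF.
* **Demography** — unfolded SFS with hypergeometric projection
  P(k | m, d, n) and a stairway-style composite Poisson likelihood
  Σ_i [ξ_i ln λ_i − λ_i], λ_i = μL·E[B_i], over piecewise-constant
  diploid histories; years = generations × 30.
* **Inbreeding** — two-state autozygosity HMM (Viterbi) → ROH
  segments; F_ROH = Σ length(ROH) / genome length.
* **Load** — deleterious = nonsynonymous with SIFT-style score < 0.05;
  per-individual HoDA/HeDA (derived-homozygous / heterozygous
  deleterious sites), 5-population Venn sharing, DAF spectrum.
* **Contemporary Ne** — Burrows composite r̂² among unlinked loci,
  sampling expectation E[r²|S] subtracted, quadratic inversion
  N̂e = (1/3 + √(1/9 − 2.76 r²′))/(2 r²′) (S ≥ 30 coefficients; small-S
  set for S < 30), delete-one-chromosome jackknife CI.
* **Structure** — binomial admixture likelihood g_il ~ Bin(2, Σ_k
  q_ik p_kl) fit by monotone EM; K selected by 10-fold entry-masking
  cross-validation.

## Worked example

The numbered drivers under `analysis/` run the full chain on a
synthetic 21-sample, 5-population cohort (10 × 1 Mb genome, 6,000
candidate sites, weak migration, 10% mildly deleterious sites):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_filter.py
...
python analysis/09_structure.py
```

Selected output from a run of the chain:

```
6000 sites in; dataset2 6000, dataset3 2011, dataset4 262
mean pairwise Hudson FST: 0.153
high-confidence calls: 5303 of 6000 sites; accuracy vs truth 0.996
70.70% of deleterious sites have DAF < 0.05
contemporary Ne = 38.5 (6.4-232.7) jackknife CI
cross-validation selects K = 1
```

Reading it: the MAF filter more than halves the SNP set and pruning
leaves 262 independent loci; differentiation among demes is weak
(FST ≈ 0.15) and — exactly as in the empirical design this mirrors —
cross-validation still prefers a single ancestral cluster.  The
ancestral-state caller polarizes 88% of sites at 99.6% accuracy
against the simulation truth, most deleterious variants segregate at
low frequency, and the LD method recovers an Ne of the order of the
simulated deme size with a wide 12-block jackknife interval.

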