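# Methods

This note documents the models, defaults and numerical choices behind
`consgen`, and what the synthetic-data validation does and does not
establish about real resequencing data.

## Scope and data model

The pipeline operates on diploid biallelic SNP matrices (samples ×
sites) with dosages {0, 1, 2, missing}, per-genotype GQ/DP where the
caller provides them, and an in-band ancestral allele (INFO/AA; `N` =
unpolarized).  Coordinates are 0-based half-open internally and
1-based in VCF; the conversion is confined to `consgen.io` and tested
on boundary positions in both directions.  The library functions and
the numbered `analysis/` drivers are the interface; each driver is a
thin narrative over one stage and writes TSV/BED/VCF artifacts under
`results/`.

## Filter chain

Genotype masking sets cells with GQ < 20 or DP < 5 to missing; cells
without those fields are left untouched and logged, never guessed.
Site filters run in a fixed order (summed depth → biallelic SNP →
missingness → MAF) so per-stage removal counts are well defined; the
depth rule keeps summed DP in the inclusive window [100, 600]
(removal is the strict "< 100 or > 600" reading), missingness removes
rates strictly above 20%, MAF removes frequencies strictly below
0.05.  LD pruning is greedy left-to-right in 50-site windows sliding
by 10 sites: for any pair with genotype-correlation r² > 0.2 the
later-position site is dropped.  The tie-break (always drop the
right-hand site) is fixed deliberately — the reference tool's choice
varies by version, and determinism matters more here than mimicry.
Correlations use mean-imputed dosages.

## Diversity statistics

Per-site estimators use the per-site called-allele count n_s, so
missing data shrinks n locally rather than dropping sites: θ̂_W sums
1/a_{n_s} over segregating sites, θ̂_π sums 2d(n−d)/(n(n−1)), both
divided by callable sites (for simulated data, the window span).  For
Tajima's D and Fu & Li's D the variance constants need a single n per
window; we use the median n_s over segregating sites.  Fu & Li's D
uses derived singletons when polarization is available and otherwise
falls back to the starred (minor-allele-singleton) variant, with the
variant recorded in the output.

Two properties of these statistics matter for calibration testing.
First, the estimator means calibrate cleanly: on 1,000 neutral
constant-size coalescent windows at θ = 0.01/site the mean θ̂_W and
θ̂_π land within Monte-Carlo error of 0.01.  Second, the *normalized*
D statistics have small negative means under neutrality at finite n
(for n = 42, ≈ −0.10 for Tajima's and ≈ −0.14 for Fu & Li's D in
both our generator and an independent msprime run with infinite-sites
mutations); a test that expects a mean of exactly 0 at high replicate
counts will therefore flag them.  The acceptance suite keeps the
0-centred check as specified and we record the bias here rather than
recentring it.

FST defaults to Hudson's estimator aggregated as a ratio of averages
(Σ numerators / Σ denominators), which is robust to rare variants and
unequal sample sizes; it includes the finite-sample within-population
correction, so identical sample frequencies give a slightly negative
value rather than 0.  A Weir–Cockerham variant is available and
labeled.  LD decay bins the Burrows-equivalent genotype r² by
pairwise distance with no monotone smoothing.

## Ancestral reconstruction and polarization

Likelihoods come from Felsenstein's pruning recursion under JC69 with
uniform base frequencies — the simplest calibrated choice given that
the original model-selection step is not reproducible without its
alignment; `N` leaves are uninformative (all-ones partials).
Marginal posteriors at any internal node use an up-down pass
(outside messages × inside partials) and are verified against
exhaustive enumeration over all joint internal-state assignments to
1e-12 on trees up to 6 taxa.  The crown node is user-specified as an
MRCA of named leaves rather than hard-coded.  Calling uses the
posterior ≥ 0.95 rule with exact ties mapped to `N`.  Polarization
flips dosages where the ancestral equals ALT, drops `N`/mismatched
sites with counts, and relabels REF/ALT to ancestral/derived so that
re-polarizing is the identity.

## SFS and demographic inference

The unfolded SFS uses hypergeometric projection: a site with m called
alleles and d derived contributes C(d,k)C(m−d,n−k)/C(m,n) to bin k.
Projection mass landing in bins 0/n (monomorphic after projection) is
tracked separately from low-coverage drops so the bookkeeping
identity bins + projected_out + dropped = S holds exactly.
Fractional counts are kept; the Poisson composite likelihood does not
need integers.

Expected spectra follow E[ξ_i] = μL·E[B_i] with E[B_i] =
Σ_k k·E[T_k]·P(i|k), P(i|k) = C(n−i−1,k−2)/C(n−1,k−1).  Single-epoch
models use the exact 4N/i.  Multi-epoch models compute E[T_k] by
Monte-Carlo averaging of coalescent intervals in rescaled time
(default 10,000–20,000 draws); the exponential draws are
parameter-free, so one seeded draw is shared across all likelihood
evaluations of a fit (common random numbers), keeping the surface
smooth for the optimizer.  The method (exact vs MC) is an attribute
of the run, not a hidden branch.

The fit maximizes Σ_i [ξ_i ln λ_i − λ_i] over per-epoch sizes on a
log10 scale (Nelder-Mead, multi-start) with epoch boundaries scanned
on a log-spaced grid of generations centred on a Watterson-based Ne
scale; 1-epoch fits use the closed-form ML.  This is deliberately a
small-epoch *stairway-style* composite-likelihood fit, not a
reimplementation of any specific tool's per-bin parameterization or
model averaging: the testable claims are parameter recovery (constant
Ne within factor 1.25 median; 10-fold-crash direction in ≥ 90% of
replicates) rather than output-file compatibility.  Whole-genome
PSMC-type inference is out of scope; for the record, the empirical
settings usually quoted for it are `-t 15 -r 5 -p "4+30*2+4+6+10"`.
Times convert to years at 30 y/generation.  The mutation-rate input
is treated as per site per generation; sources sometimes quote such
rates "per locus", and we do not attempt to resolve that ambiguity —
the rate is an explicit parameter everywhere.

## ROH and F_ROH

Autozygosity is decoded by a two-state HMM per sample and chromosome:
emissions P(het | autozygous) = 0.005 (genotype-error allowance),
P(het | background) = the sample's per-chromosome empirical
heterozygosity floored at 0.02 (the floor keeps the states
identifiable on all-homozygous chromosomes), missing = uninformative;
switch probability min(1e-8 × gap_bp, 0.49); uniform initial state.
The exact Viterbi decode equals brute-force path enumeration on all
tested toys (≤ 12 sites).  Reported segments span the outermost
homozygous sites (not flanking midpoints), require ≥ 100 kb and ≥ 25
sites by default (scaled down in the toy-genome driver), and F_ROH
divides merged segment length by a user-supplied genome length — the
choice of denominator (assembly vs callable length) is explicitly the
caller's.  The reference tool's HMM parameters are undocumented, so
these defaults are our own, fixed and exposed in config.

## Genetic load

Deleterious = nonsynonymous with score < 0.05, tolerated = ≥ 0.05;
nonsynonymous sites without scores become "other" and are logged.
HoDA/HeDA count derived-homozygous/heterozygous deleterious sites per
individual; missing genotypes count toward neither.  The species-level
"fraction homozygous" statistic counts a deleterious site as
homozygous when ≥ 1 individual is derived-homozygous (optionally
restricted to DAF > 0.05) — the wording in the field is ambiguous and
this operationalization reproduces the usual printed ratio
arithmetic.  Population presence defaults to any-derived-copy, with
an HoDA-presence mode for the stricter reading of sharing diagrams;
the Venn partition is exact and asserted disjoint/exhaustive.

## LD-based contemporary Ne

Loci are filtered (missing ≤ 5%, MAF ≥ 0.05 — rare alleles bias r²)
and thinned so kept sites are ≥ 60 kb apart, inclusive at the
boundary (the cited tool's convention is unverifiable; ours is fixed
and stated).  Pair r² is the Burrows composite Δ̂²/[(p(1−p)+D_A)
(q(1−q)+D_B)], computed on individuals called at both loci —
algebraically the squared Pearson correlation of dosages, which the
tests confirm against a direct contingency-table computation.  Pairs
are restricted to different chromosomes (or beyond a distance cutoff)
to approximate the unlinked-loci assumption.  The drift signal is
r̄² − E[r²|S] with the published random-mating regressions (S ≥ 30:
1/S + 3.19/S²; S < 30: 0.0018 + 0.907/S + 4.44/S²) at the harmonic
mean S over pairs, inverted through the matching quadratic; a
non-positive signal flags Ne = ∞ rather than a spurious number.  The
CI is a delete-one-chromosome jackknife on log Ne (≥ 3 blocks;
deletions with no pairs are skipped and logged).

## Structure and cross-validation

The admixture likelihood is binomial with f = QP; the optimizer is a
joint-M-step EM (both Q and P updated from responsibilities at the
current parameters), which is monotone in the log-likelihood — the
suite asserts non-decrease within 1e-9 on every run.  P is clipped to
[1e-6, 1−1e-6]; Q rows renormalized each iteration.  Best of
n_starts (default 5) seeded restarts.  Cross-validation masks
genotype *entries* (not whole samples) in 10 seeded folds and scores
masked entries by binomial deviance under the refit model; K is the
argmin of the mean deviance.  On simulated data this selects K = 1
for panmictic cohorts and K = 2 for two isolated demes in ≥ 80% of
replicates.

## Synthetic data: what it does and does not show

Two generators provide ground truth.  The coalescent generator builds
independent non-recombining 20-kb windows under piecewise-constant
diploid histories with infinite-sites mutation (derived = ALT truth
recorded); it is calibrated against E[ξ_i] = θ/i and against
Watterson recovery, and agrees with msprime under matched
(infinite-sites) settings.  The forward Wright-Fisher generator is
individual-based with multiplicative selection (1, 1−hs, 1−s),
deme-structured migration, optional selfing, and either explicit
crossover recombination on a chromosome map or a fast
free-recombination path for deliberately unlinked loci; standing
variation can be initialized from the neutral 1/x spectrum.
Recurrent forward-time hits on occupied sites are ignored so the
per-site ancestral truth stays single-valued.

The default synthetic cohort mirrors the empirical design this
pipeline targets — 21 diploids in 5 subpopulations (6/6/1/4/4), weak
migration, a minority class of mildly deleterious sites — on a scaled
genome (10 × 1 Mb, 6,000 candidate sites) chosen for desk runtime.
Deliberately absent from the emulation: genotype-calling error
structure correlated with depth, reference bias, gene-density and
recombination-rate heterogeneity, codon-level annotation, and linked
selection.  Passing tests therefore establish that the estimators are
implemented correctly and recover truth under their own model
assumptions — not that any particular empirical estimate is right.

Replicate counts and problem sizes in the test and acceptance runs
(1,000 calibration windows; 300 windows per demographic replicate;
120 unlinked loci per Ne replicate; ~50 windows per structure
replicate) are the package's choices for a single-CPU desk run; all
are parameters, not constants.

## Known limitations

* JC69-only substitution model for reconstruction (no rate or
  frequency heterogeneity).
* The composite SFS likelihood ignores linkage between sites, as all
  SFS-only methods do; CIs on demographic fits would need a block
  bootstrap, which is not implemented.
* The forward simulator's per-generation cost is O(N·L) (free
  recombination) or O(N·L + crossovers) and is not meant for
  chromosome-scale loads.
* Weir–Cockerham FST is a labeled convenience implementation for
  two populations, not the multi-population ANOVA machinery.
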