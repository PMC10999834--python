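"""Synthetic genotype data with known truth.

Two generators cover the pipeline's needs: a coalescent simulator of
independent non-recombining windows under a piecewise-constant
demography (fast, used for spectrum and diversity calibration) and a
discrete-generation Wright-Fisher forward simulator with selection,
migration and recombination (used where linkage, inbreeding or load
truth is required).  Both are deterministic given their seed.

Mutation follows the infinite-sites idealization; in forward mode a new
mutation landing on a site that already carries one is ignored, so the
ancestral state of every site stays single-valued.
"""

from __future__ import annotations

import math

import numpy as np

from .core import (DemographicModel, GenotypeMatrix, ParameterError,
                   SimTruth)

BASES = "ACGT"

# Default study design mirrored by the synthetic cohort: 21 diploids in
# 5 relict subpopulations of sizes 6/6/1/4/4.
DEFAULT_POP_SIZES = {"DLS": 6, "FD": 6, "MAD": 1, "MC": 4, "XZQ": 4}


# ---------------------------------------------------------------------------
# time rescaling for piecewise-constant demographies

def time_map(model: DemographicModel):
    """Return (rescaled breakpoints R, generation breakpoints G, sizes N).

    Rescaled (coalescent) time tau relates to generations t through
    d tau = dt / (2 N(t)); both axes share epoch breakpoints so the map
    is piecewise linear.
    """
    durations = np.array([d for d, _ in model.epochs], dtype=float)
    sizes = np.array([n for _, n in model.epochs], dtype=float)
    finite = durations[:-1]
    G = np.concatenate([[0.0], np.cumsum(finite)])
    R = np.concatenate([[0.0], np.cumsum(finite / (2 * sizes[:-1]))])
    return R, G, sizes


def rescaled_to_generations(tau: np.ndarray, model: DemographicModel) -> np.ndarray:
    """Map rescaled coalescent times to generations (piecewise linear)."""
    R, G, sizes = time_map(model)
    tau = np.asarray(tau, dtype=float)
    out = tau * (2 * sizes[0])
    for j in range(1, len(R)):
        sel = tau >= R[j]
        if sel.any():
            out[sel] = G[j] + (tau[sel] - R[j]) * (2 * sizes[j])
    return out


def sample_coalescent_times(n: int, model: DemographicModel,
                            rng: np.random.Generator,
                            size: int = 1) -> np.ndarray:
    """Event times (generations) of the n-1 coalescences, shape (size, n-1).

    Column j is the time at which the number of lineages drops from
    n - j to n - j - 1.
    """
    ks = np.arange(n, 1, -1)
    rates = ks * (ks - 1) / 2.0
    waits = rng.exponential(1.0, size=(size, n - 1)) / rates
    return rescaled_to_generations(np.cumsum(waits, axis=1), model)


# ---------------------------------------------------------------------------
# coalescent window generator

def _simulate_window(n: int, model: DemographicModel, lam_per_gen: float,
                     rng: np.random.Generator):
    """One non-recombining genealogy; returns (carrier_masks, counts).

    ``carrier_masks`` is a list of leaf-set bitmasks, one per branch
    with >= 1 mutation; ``counts`` the number of mutations per such
    branch.  ``lam_per_gen`` is the whole-window mutation rate per
    generation per lineage.
    """
    times = sample_coalescent_times(n, model, rng)[0]
    node_time = np.zeros(2 * n - 1)
    node_time[n:] = times
    masks = np.zeros(2 * n - 1, dtype=np.uint64)
    masks[:n] = np.uint64(1) << np.arange(n, dtype=np.uint64)
    active = list(range(n))
    parent_time = np.empty(2 * n - 2)
    for j in range(n - 1):
        i1 = active.pop(rng.integers(len(active)))
        i2 = active.pop(rng.integers(len(active)))
        new = n + j
        masks[new] = masks[i1] | masks[i2]
        parent_time[i1] = times[j]
        parent_time[i2] = times[j]
        active.append(new)
    lengths = parent_time - node_time[: 2 * n - 2]
    muts = rng.poisson(lam_per_gen * lengths)
    hit = muts > 0
    return masks[: 2 * n - 2][hit], muts[hit]


def simulate_coalescent_windows(n_haplotypes: int, model: DemographicModel,
                                theta_per_window: float, n_windows: int,
                                seed: int,
                                window_length: int = 20_000
                                ) -> tuple[GenotypeMatrix, SimTruth]:
    """Independent coalescent windows; diploids formed by pairing haplotypes.

    ``theta_per_window`` is 4*N0*mu_window with N0 the most recent
    epoch size, so the per-generation whole-window mutation rate is
    theta/(4*N0).  Each window gets its own chromosome label and
    uniformly drawn distinct site positions in [0, window_length).
    Derived alleles are coded as ALT and the ancestral truth is REF.
    """
    if n_haplotypes % 2:
        raise ParameterError("n_haplotypes must be even (diploid pairing)")
    if n_haplotypes > 64:
        raise ParameterError("n_haplotypes > 64 unsupported (bitmask carrier sets)")
    if theta_per_window <= 0:
        raise ParameterError("theta must be positive")
    if n_windows < 1:
        raise ParameterError("n_windows must be >= 1")
    rng = np.random.default_rng(seed)
    n0 = model.epochs[0][1]
    lam = theta_per_window / (4.0 * n0)
    n_dip = n_haplotypes // 2
    hap_idx = np.arange(n_haplotypes, dtype=np.uint64)
    chroms, positions, columns = [], [], []
    width = len(str(n_windows))
    for w in range(n_windows):
        masks, counts = _simulate_window(n_haplotypes, model, lam, rng)
        s = int(counts.sum())
        if s == 0:
            continue
        if s > window_length:  # infinite-sites cap; effectively unreachable
            s = window_length
        pos = np.sort(rng.choice(window_length, size=s, replace=False))
        branch = np.repeat(masks, counts)[:s]
        carriers = ((branch[:, None] >> hap_idx[None, :]) & np.uint64(1)
                    ).astype(np.int16)
        dosage = carriers[:, 0::2] + carriers[:, 1::2]  # (s, n_dip)
        chroms.append(np.full(s, f"w{w:0{width}d}", dtype=object))
        positions.append(pos)
        columns.append(dosage)
    if chroms:
        chrom = np.concatenate(chroms)
        pos = np.concatenate(positions)
        dosage = np.concatenate(columns, axis=0).T.astype(np.int16)
    else:
        chrom = np.array([], dtype=object)
        pos = np.array([], dtype=np.int64)
        dosage = np.zeros((n_dip, 0), dtype=np.int16)
    n_sites = len(pos)
    matrix = GenotypeMatrix(
        sample_ids=[f"s{i+1}" for i in range(n_dip)],
        chrom=chrom, pos=pos.astype(np.int64),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        ancestral=np.full(n_sites, "A", dtype=object),
        dosage=dosage,
    )
    truth = SimTruth(
        ancestral=np.full(n_sites, "A", dtype=object),
        population=["POP"] * n_dip,
        derived_freq=(dosage.sum(axis=0) / n_haplotypes if n_sites
                      else np.array([])),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Wright-Fisher forward generator

DEFAULT_CHROM_MAP = [(f"chr{i+1}", 1_000_000) for i in range(20)]


def _site_layout(L_sites: int, chromosome_map, rng: np.random.Generator):
    lengths = np.array([l for _, l in chromosome_map], dtype=float)
    counts = np.floor(L_sites * lengths / lengths.sum()).astype(int)
    for i in range(L_sites - counts.sum()):
        counts[i % len(counts)] += 1
    chroms, poss, slices = [], [], []
    start = 0
    for (name, length), c in zip(chromosome_map, counts):
        pos = np.sort(rng.choice(length, size=c, replace=False))
        chroms.append(np.full(c, name, dtype=object))
        poss.append(pos)
        slices.append((start, start + c, length))
        start += c
    return np.concatenate(chroms), np.concatenate(poss).astype(np.int64), slices


def _standing_frequencies(L: int, rng: np.random.Generator,
                          n_total_haps: int) -> np.ndarray:
    """Initial derived frequencies from the neutral 1/x spectrum."""
    xmin = 1.0 / n_total_haps
    xmax = 1.0 - xmin
    u = rng.random(L)
    return xmin * (xmax / xmin) ** u


def _recombine(h1: np.ndarray, h2: np.ndarray, slices, site_pos,
               recomb_per_bp: float, rng: np.random.Generator) -> np.ndarray:
    """One gamete as a crossover mosaic of the two parental haplotypes."""
    gamete = np.empty_like(h1)
    for a, b, length in slices:
        k = rng.poisson(recomb_per_bp * length)
        phase = rng.integers(2)
        if k == 0:
            gamete[a:b] = h1[a:b] if phase == 0 else h2[a:b]
            continue
        cross = np.sort(rng.integers(0, length, size=k))
        parity = (np.searchsorted(cross, site_pos[a:b], side="right")
                  + phase) % 2
        seg1 = h1[a:b]
        seg2 = h2[a:b]
        gamete[a:b] = np.where(parity == 0, seg1, seg2)
    return gamete


def simulate_wright_fisher_forward(
        N_diploid, L_sites: int, n_generations: int,
        sample_sizes_per_pop, seed: int,
        chromosome_map=None, recomb_per_bp: float | None = None,
        mu: float = 0.0, selection_config=None,
        migration_matrix=None, init: str = "standing",
        selfing_rate: float = 0.0, pop_names=None,
        ) -> tuple[GenotypeMatrix, SimTruth]:
    """Discrete-generation Wright-Fisher simulation of one or more demes.

    Parameters
    ----------
    N_diploid : int or sequence of int
        Diploid deme sizes (constant through time).
    L_sites : int
        Number of candidate sites, laid out on ``chromosome_map``.
    recomb_per_bp : float or None
        Per-bp crossover probability per meiosis.  ``None`` selects a
        fast free-recombination path (independent Mendelian sampling
        per site), appropriate when loci are meant to be unlinked.
    selection_config : list of dict, optional
        Each entry ``{"name", "fraction", "s", "h"}``; sites are
        assigned classes by fraction, fitness is multiplicative with
        genotype fitnesses 1, 1-hs, 1-s for 0/1/2 derived copies.
    migration_matrix : (D, D) array, optional
        ``m[i][j]`` = probability an offspring born in deme i draws its
        parents from deme j; rows must sum to <= 1 off-diagonal
        (diagonal is filled with the remainder).
    init : "standing" or "monomorphic"
        Standing variation draws initial derived frequencies from the
        neutral 1/x spectrum, shared across demes.
    """
    sizes = np.atleast_1d(np.asarray(N_diploid, dtype=int))
    if np.any(sizes < 2):
        raise ParameterError("N_diploid must be >= 2")
    D = len(sizes)
    sample_sizes = np.atleast_1d(np.asarray(sample_sizes_per_pop, dtype=int))
    if len(sample_sizes) != D or np.any(sample_sizes > sizes):
        raise ParameterError("sample sizes must be given per deme and fit in it")
    rng = np.random.default_rng(seed)
    if chromosome_map is None:
        chromosome_map = DEFAULT_CHROM_MAP
    chrom, pos, slices = _site_layout(L_sites, chromosome_map, rng)

    if migration_matrix is None:
        mig = np.eye(D)
    else:
        mig = np.array(migration_matrix, dtype=float)
        off = mig.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off.sum(axis=1) > 1 + 1e-12) or np.any(off < 0):
            raise ParameterError("off-diagonal migration rows must sum to <= 1")
        np.fill_diagonal(mig, 1.0 - off.sum(axis=1))

    if selection_config is None:
        selection_config = [{"name": "neutral", "fraction": 1.0,
                             "s": 0.0, "h": 0.5}]
    fracs = np.array([c["fraction"] for c in selection_config], dtype=float)
    if not math.isclose(fracs.sum(), 1.0, rel_tol=1e-9):
        raise ParameterError("selection class fractions must sum to 1")
    class_idx = rng.choice(len(selection_config), size=L_sites, p=fracs)
    s_arr = np.array([c["s"] for c in selection_config])[class_idx]
    h_arr = np.array([c["h"] for c in selection_config])[class_idx]
    class_names = np.array([c["name"] for c in selection_config],
                           dtype=object)[class_idx]
    has_selection = np.any(s_arr != 0)
    # per-site log fitness of het / hom-derived genotypes
    log_w_het = np.log1p(-np.clip(h_arr * s_arr, None, 0.999999))
    log_w_hom = np.log1p(-np.clip(s_arr, None, 0.999999))

    total_haps = int(2 * sizes.sum())
    if isinstance(init, np.ndarray):  # explicit per-site initial frequencies
        freqs = np.broadcast_to(init.astype(float), (L_sites,))
        haps = [(rng.random((2 * n, L_sites)) < freqs).astype(np.int8)
                for n in sizes]
        occupied = np.ones(L_sites, dtype=bool)
    elif init == "standing":
        freqs = _standing_frequencies(L_sites, rng, total_haps)
        haps = [(rng.random((2 * n, L_sites)) < freqs).astype(np.int8)
                for n in sizes]
        occupied = np.ones(L_sites, dtype=bool)
    elif init == "monomorphic":
        haps = [np.zeros((2 * n, L_sites), dtype=np.int8) for n in sizes]
        occupied = np.zeros(L_sites, dtype=bool)
    else:
        raise ParameterError(f"unknown init mode {init!r}")

    hap_offsets = np.concatenate([[0], np.cumsum(2 * sizes)])

    for _ in range(n_generations):
        # fitness per individual per deme
        if has_selection:
            weights = []
            for d in range(D):
                g = haps[d][0::2] + haps[d][1::2]
                logw = ((g == 1) @ log_w_het) + ((g == 2) @ log_w_hom)
                w = np.exp(logw - logw.max())
                weights.append(w / w.sum())
        else:
            weights = [None] * D
        new_haps = []
        for d in range(D):
            nd = sizes[d]
            src = rng.choice(D, size=nd, p=mig[d])
            mothers = np.empty(nd, dtype=int)
            fathers = np.empty(nd, dtype=int)
            for j in np.unique(src):
                sel = src == j
                k = int(sel.sum())
                mothers[sel] = hap_offsets[j] // 2 + rng.choice(
                    sizes[j], size=k, p=weights[j])
                fathers[sel] = hap_offsets[j] // 2 + rng.choice(
                    sizes[j], size=k, p=weights[j])
            if selfing_rate > 0:
                selfed = rng.random(nd) < selfing_rate
                fathers[selfed] = mothers[selfed]
            pool = np.concatenate(haps, axis=0)
            child = np.empty((2 * nd, L_sites), dtype=np.int8)
            if recomb_per_bp is None:
                for parents, out_slice in ((mothers, slice(0, None, 2)),
                                           (fathers, slice(1, None, 2))):
                    h1 = pool[2 * parents]
                    h2 = pool[2 * parents + 1]
                    pick = rng.random((nd, L_sites)) < 0.5
                    child[out_slice] = np.where(pick, h1, h2)
            else:
                for i in range(nd):
                    child[2 * i] = _recombine(
                        pool[2 * mothers[i]], pool[2 * mothers[i] + 1],
                        slices, pos, recomb_per_bp, rng)
                    child[2 * i + 1] = _recombine(
                        pool[2 * fathers[i]], pool[2 * fathers[i] + 1],
                        slices, pos, recomb_per_bp, rng)
            new_haps.append(child)
        haps = new_haps
        if mu > 0:
            n_new = rng.poisson(total_haps * L_sites * mu)
            if n_new:
                tgt_hap = rng.integers(total_haps, size=n_new)
                tgt_site = rng.integers(L_sites, size=n_new)
                fresh = ~occupied[tgt_site]
                for hh, ss in zip(tgt_hap[fresh], tgt_site[fresh]):
                    if not occupied[ss]:
                        deme = np.searchsorted(hap_offsets, hh, side="right") - 1
                        haps[deme][hh - hap_offsets[deme], ss] = 1
                        occupied[ss] = True

    if pop_names is None:
        pop_names = [f"P{d+1}" for d in range(D)]
    sample_ids, rows, pops = [], [], []
    for d in range(D):
        chosen = rng.choice(sizes[d], size=sample_sizes[d], replace=False)
        for i in chosen:
            rows.append(haps[d][2 * i] + haps[d][2 * i + 1])
            sample_ids.append(f"{pop_names[d]}_{i+1}")
            pops.append(pop_names[d])
    dosage = np.array(rows, dtype=np.int16)
    pooled = np.concatenate(haps, axis=0)
    matrix = GenotypeMatrix(
        sample_ids=sample_ids, chrom=chrom, pos=pos,
        ref=np.full(L_sites, "A", dtype=object),
        alt=np.full(L_sites, "T", dtype=object),
        ancestral=np.full(L_sites, "A", dtype=object),
        dosage=dosage,
    )
    admix = np.zeros((len(sample_ids), D))
    for i, p in enumerate(pops):
        admix[i, pop_names.index(p)] = 1.0
    truth = SimTruth(
        ancestral=np.full(L_sites, "A", dtype=object),
        population=pops, admixture=admix,
        selection_s=s_arr, site_class=class_names,
        derived_freq=pooled.mean(axis=0),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# annotations and outgroup states

def simulate_gene_intervals(chromosome_map, seed: int,
                            mean_gene_length: int = 2_000,
                            genes_per_mb: float = 10.0):
    """Seeded random gene intervals (0-based half-open) per chromosome."""
    rng = np.random.default_rng(seed)
    intervals = []
    for name, length in chromosome_map:
        n_genes = rng.poisson(genes_per_mb * length / 1e6)
        starts = np.sort(rng.integers(0, max(1, length - mean_gene_length),
                                      size=n_genes))
        for s in starts:
            intervals.append((name, int(s), int(min(length, s + mean_gene_length))))
    return intervals


def attach_annotations(matrix: GenotypeMatrix, fractions: dict,
                       score_distributions: dict | None = None,
                       seed: int = 0, gene_intervals=None,
                       flank: int = 5_000):
    """Assign functional classes and deleteriousness scores to sites.

    ``fractions`` gives class probabilities over {synonymous,
    nonsynonymous} (an optional "other" remainder is allowed).
    Nonsynonymous sites draw a score from a two-part mixture with
    ``score_distributions["deleterious_mass"]`` of its mass uniform on
    [0, 0.05) and the rest uniform on [0.05, 1], so the expected
    fraction scoring below the SIFT 0.05 cutoff is the stated mass.
    """
    from .core import AnnotationTable
    probs = {k: float(v) for k, v in fractions.items()}
    total = sum(probs.values())
    if not math.isclose(total, 1.0, rel_tol=1e-9) or min(probs.values()) < 0:
        raise ParameterError("class fractions must be non-negative and sum to 1")
    mass = 0.3 if score_distributions is None else float(
        score_distributions.get("deleterious_mass", 0.3))
    if not 0 <= mass <= 1:
        raise ParameterError("deleterious_mass must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = list(probs)
    klass = rng.choice(labels, size=matrix.n_sites,
                       p=[probs[k] for k in labels]).astype(object)
    score = np.full(matrix.n_sites, np.nan)
    nonsyn = klass == "nonsynonymous"
    n_ns = int(nonsyn.sum())
    if n_ns:
        low = rng.random(n_ns) < mass
        draws = np.where(low, rng.random(n_ns) * 0.05,
                         0.05 + rng.random(n_ns) * 0.95)
        score[nonsyn] = draws
    near = np.zeros(matrix.n_sites, dtype=bool)
    if gene_intervals:
        for c, s, e in gene_intervals:
            on = matrix.chrom == c
            near |= on & (matrix.pos >= s - flank) & (matrix.pos < e + flank)
    return AnnotationTable(chrom=matrix.chrom.copy(), pos=matrix.pos.copy(),
                           klass=klass, score=score, near_gene=near)


def _jc_evolve(states: np.ndarray, branch: float,
               rng: np.random.Generator) -> np.ndarray:
    """Evolve integer base states along a branch under Jukes-Cantor."""
    p_same = 0.25 + 0.75 * np.exp(-4.0 * branch / 3.0)
    stay = rng.random(len(states)) < p_same
    shifted = (states + 1 + rng.integers(3, size=len(states))) % 4
    return np.where(stay, states, shifted)


def simulate_outgroup_alignment(tree, root_states, mu_branch: float = 1.0,
                                seed: int = 0):
    """Evolve per-site states down a rooted tree under Jukes-Cantor.

    ``root_states`` is an array of bases (the recorded truth, e.g. an
    ingroup consensus); branch lengths are expected substitutions per
    site, scaled by ``mu_branch``.  Returns ``{leaf_name: base array}``.
    """
    rng = np.random.default_rng(seed)
    base_to_int = {b: i for i, b in enumerate(BASES)}
    root = np.array([base_to_int[b] for b in root_states])
    out: dict[str, np.ndarray] = {}

    def walk(clade, states):
        for child in clade.clades:
            b = (child.branch_length or 0.0) * mu_branch
            child_states = _jc_evolve(states, b, rng)
            if child.is_terminal():
                out[child.name] = np.array([BASES[i] for i in child_states],
                                           dtype=object)
            else:
                walk(child, child_states)

    walk(tree.root, root)
    if tree.root.is_terminal():  # degenerate single-leaf tree
        out[tree.root.name] = np.array([BASES[i] for i in root], dtype=object)
    return out
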