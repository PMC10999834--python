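"""Diversity estimators against hand-derived values and independent
textbook-formula oracles (constants evaluated one by one in the test)."""

import numpy as np
import pytest

from consgen import diversity, simulate
from consgen.core import DemographicModel, PopulationMap
from conftest import make_matrix


def oracle_tajima_d(n, S, pi_count):
    """Independent constant-by-constant evaluation of Tajima's D."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (pi_count - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def oracle_fu_li_d(n, eta, eta_e):
    """Independent evaluation of Fu & Li's D (outgroup variant)."""
    an = sum(1.0 / i for i in range(1, n))
    bn = sum(1.0 / i ** 2 for i in range(1, n))
    cn = 2.0 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    vd = 1.0 + an ** 2 / (bn + an ** 2) * (cn - (n + 1) / (n - 1.0))
    ud = an - 1.0 - vd
    return (eta - an * eta_e) / np.sqrt(ud * eta + vd * eta ** 2)


class TestWatterson:
    def test_hand_value_n4_s3(self):
        # 2 diploids = 4 alleles, S=3, a_3 = 1 + 1/2 + 1/3, 100 callable
        m = make_matrix([[1, 0, 1], [0, 1, 1]])
        assert diversity.watterson_theta(m, 100) == pytest.approx(
            3 / ((1 + 0.5 + 1 / 3) * 100), abs=1e-9)

    def test_monomorphic_window_is_zero(self):
        m = make_matrix([[0, 2], [0, 2]])
        assert diversity.watterson_theta(m, 50) == 0.0

    def test_zero_callable_flagged(self):
        m = make_matrix([[1]])
        assert np.isnan(diversity.watterson_theta(m, 0))


class TestPi:
    def test_two_haplotypes_two_of_hundred(self):
        # two haploid sequences differing at 2 of 100 sites == one diploid
        # sample het at 2 sites: pi = 2 * (2*1*1/(2*1)) / 100 = 0.02
        dos = np.zeros((1, 2), dtype=int) + 1
        m = make_matrix(dos)
        assert diversity.nucleotide_diversity(m, 100) == pytest.approx(0.02)

    def test_per_site_closed_form_n42(self):
        # p = 0.5 with n = 42 alleles: 2pq * n/(n-1) = 0.5 * 42/41
        dos = np.ones((21, 1), dtype=int)
        m = make_matrix(dos)
        assert diversity.per_site_pi(m)[0] == pytest.approx(0.5 * 42 / 41)

    def test_equals_bruteforce_mean_pairwise_difference(self, rng):
        # phased toy: diploids formed from explicit haplotypes
        haps = rng.integers(0, 2, size=(8, 30))
        dos = haps[0::2] + haps[1::2]
        m = make_matrix(dos)
        n = 8
        acc = 0
        for i in range(n):
            for j in range(i + 1, n):
                acc += (haps[i] != haps[j]).sum()
        brute = acc / (n * (n - 1) / 2) / 30
        # estimator is unbiased for the same quantity; with full data and
        # per-site counts it equals the pairwise average exactly
        assert diversity.nucleotide_diversity(m, 30) == pytest.approx(brute)


class TestTajimasD:
    def test_zero_when_estimators_agree(self):
        # construct window where pi_count == S/a1 is impossible by hand;
        # instead check the sign property on both sides of zero
        m = make_matrix([[1, 1], [1, 1], [1, 1], [0, 0]])  # intermediate freq
        assert diversity.tajimas_d(m) > 0
        m2 = make_matrix([[1, 0], [0, 1], [0, 0], [0, 0]])  # singletons
        assert diversity.tajimas_d(m2) < 0

    def test_textbook_example_n10_s16(self):
        # classic worked example: n=10, S=16, mean pairwise diff 3.888
        d = oracle_tajima_d(10, 16, 3.888)
        # package formula evaluated through its constants
        tc = diversity.tajima_constants(10)
        ours = (3.888 - 16 / tc["a1"]) / np.sqrt(
            tc["e1"] * 16 + tc["e2"] * 16 * 15)
        assert ours == pytest.approx(d, abs=1e-6)

    def test_matches_oracle_on_simulated_windows(self):
        model = DemographicModel([(np.inf, 5_000)])
        mat, _ = simulate.simulate_coalescent_windows(
            10, model, 10.0, n_windows=50, seed=41, window_length=2_000)
        for c in dict.fromkeys(mat.chrom.tolist()):
            sub = mat.take_sites(mat.chrom == c)
            d = sub.dosage.sum(axis=0)
            n = 10
            seg = (d > 0) & (d < n)
            S = int(seg.sum())
            if S < 2:
                continue
            pi_count = float(np.sum(2 * d[seg] * (n - d[seg])
                                    / (n * (n - 1))))
            assert diversity.tajimas_d(sub) == pytest.approx(
                oracle_tajima_d(n, S, pi_count), abs=1e-6)


class TestFuLiD:
    def test_no_singletons_gives_positive_sign(self):
        m = make_matrix([[1, 1], [1, 1], [0, 0], [0, 0]], polarized=True)
        stat, variant = diversity.fu_li_d(m)
        assert variant == "D" and stat > 0

    def test_matches_independent_formula(self):
        m_dos = np.array([[1, 0, 1, 0], [1, 0, 0, 0], [0, 1, 1, 0],
                          [0, 0, 1, 1], [0, 0, 1, 0]])
        m = make_matrix(m_dos, polarized=True)
        d = m_dos.sum(axis=0)
        n = 10
        seg = (d > 0) & (d < n)
        eta = int(seg.sum())
        eta_e = int(np.sum(seg & (d == 1)))
        stat, variant = diversity.fu_li_d(m)
        assert variant == "D"
        assert stat == pytest.approx(oracle_fu_li_d(n, eta, eta_e), abs=1e-6)

    def test_starred_variant_without_polarization(self):
        m = make_matrix([[1, 0], [0, 1], [0, 0], [0, 0]])
        stat, variant = diversity.fu_li_d(m)
        assert variant == "D*" and np.isfinite(stat)


class TestHeterozygosity:
    def test_all_homozygous_is_zero(self):
        m = make_matrix([[0, 2, 0], [2, 0, 2]])
        df = diversity.individual_heterozygosity(m, 1_000)
        assert df["het_rate"].tolist() == [0.0, 0.0]

    def test_simple_rate(self):
        dos = np.zeros((1, 10), dtype=int)
        dos[0, :10] = 1
        m = make_matrix(dos)
        df = diversity.individual_heterozygosity(m, 1_000)
        assert df["het_rate"][0] == pytest.approx(0.01)

    def test_matches_truth_frequencies_at_equilibrium(self):
        model = DemographicModel([(np.inf, 5_000)])
        mat, truth = simulate.simulate_coalescent_windows(
            20, model, 20.0, n_windows=400, seed=43, window_length=2_000)
        # expected het per site from truth frequencies (binomial sampling)
        p = truth.derived_freq
        expected = np.sum(2 * p * (1 - p) * 20 / 19) / (400 * 2_000)
        df = diversity.individual_heterozygosity(mat, 400 * 2_000)
        obs = df["het_rate"].mean()
        se = df["het_rate"].std() / np.sqrt(len(df))
        assert abs(obs - expected) < 3 * max(se, 1e-5)


class TestFst:
    def _two_pop_map(self, n1, n2):
        ids = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
        return ids, PopulationMap({s: ("A" if s.startswith("a") else "B")
                                   for s in ids})

    def test_identical_frequencies_leave_only_sampling_correction(self):
        # identical sample frequencies zero the (p1-p2)^2 signal; what
        # remains is the estimator's finite-sample correction, negative
        # and equal to -[p(1-p)/(n1-1) + p(1-p)/(n2-1)] / [2p(1-p)]
        ids, pm = self._two_pop_map(4, 4)
        dos = np.tile([0, 1, 2, 1], (2, 1)).T  # same columns in both pops
        dos = np.vstack([dos, dos])
        m = make_matrix(dos, sample_ids=ids)
        res = diversity.pairwise_fst(m, pm)[0]
        p, n = 0.5, 8
        expected = (-2 * p * (1 - p) / (n - 1)) / (2 * p * (1 - p))
        assert res.fst == pytest.approx(expected, abs=1e-12)
        assert res.fst < 0

    def test_fixed_difference_gives_one(self):
        ids, pm = self._two_pop_map(3, 3)
        dos = np.array([[0] * 2] * 3 + [[2] * 2] * 3)
        m = make_matrix(dos, sample_ids=ids)
        assert diversity.pairwise_fst(m, pm)[0].fst == pytest.approx(1.0)

    def test_hand_evaluated_hudson_single_site(self):
        # p1=0.2, p2=0.8, n1=n2=10 alleles
        ids, pm = self._two_pop_map(5, 5)
        dos = np.array([[1], [1], [0], [0], [0],
                        [2], [2], [2], [1], [1]])
        m = make_matrix(dos, sample_ids=ids)
        p1, p2, n1, n2 = 0.2, 0.8, 10, 10
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) \
            - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        assert diversity.pairwise_fst(m, pm)[0].fst == pytest.approx(
            num / den, abs=1e-9)

    def test_scale_invariance_under_site_duplication(self, rng):
        ids, pm = self._two_pop_map(5, 5)
        dos = rng.integers(0, 3, size=(10, 40))
        m1 = make_matrix(dos, sample_ids=ids)
        m2 = make_matrix(np.hstack([dos, dos]),
                         pos=np.arange(80) * 50, sample_ids=ids)
        f1 = diversity.pairwise_fst(m1, pm)[0].fst
        f2 = diversity.pairwise_fst(m2, pm)[0].fst
        assert f1 == pytest.approx(f2, abs=1e-12)


class TestLdDecay:
    def test_duplicated_site_bin_is_one(self):
        dos = np.array([[0, 0], [1, 1], [2, 2], [1, 1]])
        m = make_matrix(dos, pos=[0, 2_500])
        df = diversity.ld_decay(m, max_dist=10_000, bin_width=1_000)
        assert df.loc[2, "mean_r2"] == pytest.approx(1.0)
        assert df.loc[2, "n_pairs"] == 1

    def test_linked_forward_sim_shows_decay(self):
        mat, _ = simulate.simulate_wright_fisher_forward(
            N_diploid=40, L_sites=300, n_generations=60,
            sample_sizes_per_pop=[40], seed=47,
            chromosome_map=[("chr1", 200_000)], recomb_per_bp=1e-7)
        # keep polymorphic sites
        alt, called = mat.allele_counts()
        p = alt / called
        mat = mat.take_sites((p > 0.05) & (p < 0.95))
        df = diversity.ld_decay(mat, max_dist=200_000, bin_width=20_000)
        ok = df.dropna()
        first = ok["mean_r2"].iloc[0]
        last = ok["mean_r2"].iloc[-1]
        assert first > last

    def test_free_recombination_is_flat_in_distance(self):
        mat, _ = simulate.simulate_wright_fisher_forward(
            N_diploid=100, L_sites=200, n_generations=10,
            sample_sizes_per_pop=[100], seed=48,
            chromosome_map=[("chr1", 1_000_000)], recomb_per_bp=None)
        alt, called = mat.allele_counts()
        p = alt / called
        mat = mat.take_sites((p > 0.1) & (p < 0.9))
        df = diversity.ld_decay(mat, max_dist=1_000_000, bin_width=100_000)
        ok = df.dropna()
        x = (ok["dist_low"] + ok["dist_high"]) / 2
        slope, intercept = np.polyfit(x, ok["mean_r2"], 1,
                                      w=np.sqrt(ok["n_pairs"]))
        # regression slope indistinguishable from zero
        resid = ok["mean_r2"] - (slope * x + intercept)
        se = np.sqrt(np.sum(resid ** 2) / (len(ok) - 2)
                     / np.sum((x - x.mean()) ** 2))
        assert abs(slope) < 3 * se


class TestWindowInvariants:
    def test_window_tiling_overlap_and_cover(self):
        m = make_matrix([[1] * 4], pos=[0, 15_000, 30_000, 44_000])
        ws = diversity.window_stats(m, chrom_lengths={"chr1": 45_000})
        starts = ws["start"].tolist()
        ends = ws["end"].tolist()
        # consecutive 20-kb windows at 10-kb step; last one truncated so
        # the union covers [0, chrom_length) exactly
        assert starts == [0, 10_000, 20_000, 30_000]
        assert ends == [20_000, 30_000, 40_000, 45_000]
        assert all(e - s == 10_000
                   for s, e in zip(starts[1:], ends[:-1]))

    def test_d_sign_matches_theta_difference(self, rng):
        model = DemographicModel([(np.inf, 5_000)])
        mat, _ = simulate.simulate_coalescent_windows(
            10, model, 15.0, n_windows=40, seed=51, window_length=5_000)
        ws = diversity.window_stats(
            mat, window=5_000, step=5_000,
            chrom_lengths={c: 5_000 for c in dict.fromkeys(mat.chrom)})
        ok = ws.dropna(subset=["tajimas_d"])
        a1 = {n: sum(1 / i for i in range(1, n)) for n in [10]}
        # sign(D) == sign(pi_count - S/a1) with no missing data
        pi_count = ok["theta_pi"] * ok["callable_sites"]
        tw_count = ok["S"] / a1[10]
        assert np.all(np.sign(ok["tajimas_d"]) ==
                      np.sign(pi_count - tw_count))

    def test_bottleneck_positive_expansion_negative_mean_d(self):
        bottleneck = DemographicModel([(100.0, 200), (np.inf, 20_000)])
        expansion = DemographicModel([(2_000.0, 20_000), (np.inf, 200)])
        out = {}
        for name, model in (("bott", bottleneck), ("expa", expansion)):
            mat, _ = simulate.simulate_coalescent_windows(
                10, model, 10.0, n_windows=200, seed=53,
                window_length=5_000)
            ws = diversity.window_stats(
                mat, window=5_000, step=5_000,
                chrom_lengths={c: 5_000 for c in dict.fromkeys(mat.chrom)})
            out[name] = ws["tajimas_d"].mean()
        assert out["bott"] > 0 > out["expa"]
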