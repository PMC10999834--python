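"""Generator contracts: neutral expectations, determinism, truth bookkeeping."""

import numpy as np
import pytest
from scipy.stats import chisquare

from consgen import simulate
from consgen.core import DemographicModel, ParameterError

CONST = DemographicModel([(np.inf, 10_000)], mu=1.25e-7)


class TestCoalescentWindows:
    def test_mean_sfs_proportional_to_one_over_i(self):
        # E[xi_i] = theta/i for the neutral constant-size coalescent
        mat, _ = simulate.simulate_coalescent_windows(
            4, CONST, theta_per_window=1.0, n_windows=50_000, seed=11,
            window_length=1_000)
        counts = mat.dosage.sum(axis=0)  # derived allele count per site
        xi = np.array([(counts == i).sum() for i in (1, 2, 3)]) / 50_000
        se = np.sqrt(xi / 50_000)
        expected = np.array([1.0, 0.5, 1.0 / 3.0])
        assert np.all(np.abs(xi - expected) < 3 * np.maximum(se, 1e-4))

    def test_same_seed_is_bitwise_identical(self):
        a, _ = simulate.simulate_coalescent_windows(8, CONST, 5.0, 50, seed=3)
        b, _ = simulate.simulate_coalescent_windows(8, CONST, 5.0, 50, seed=3)
        np.testing.assert_array_equal(a.dosage, b.dosage)
        np.testing.assert_array_equal(a.pos, b.pos)

    def test_watterson_recovers_input_theta(self):
        theta = 8.0
        mat, _ = simulate.simulate_coalescent_windows(
            10, CONST, theta, n_windows=1_500, seed=5, window_length=2_000)
        a9 = sum(1.0 / i for i in range(1, 10))
        import pandas as pd
        S_per = pd.Series(mat.chrom).value_counts().reindex(
            [f"w{w:04d}" for w in range(1500)]).fillna(0).to_numpy()
        est = S_per / a9
        se = est.std() / np.sqrt(len(est))
        assert abs(est.mean() - theta) < 3 * se

    def test_crash_raises_tajimas_d_relative_to_constant(self):
        # recent 100-fold crash leaves intermediate-frequency excess
        crash = DemographicModel([(50.0, 100), (np.inf, 10_000)])
        from consgen import diversity
        means = {}
        for name, model, theta in (("const", CONST, 20.0),
                                   ("crash", crash, 20.0)):
            mat, _ = simulate.simulate_coalescent_windows(
                10, model, theta, n_windows=200, seed=17, window_length=5_000)
            ws = diversity.window_stats(
                mat, window=5_000, step=5_000,
                chrom_lengths={c: 5_000 for c in dict.fromkeys(mat.chrom)})
            means[name] = ws["tajimas_d"].mean()
        assert means["crash"] > means["const"]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            simulate.simulate_coalescent_windows(5, CONST, 1.0, 10, seed=0)
        with pytest.raises(ParameterError):
            simulate.simulate_coalescent_windows(4, CONST, -1.0, 10, seed=0)


class TestForwardSimulator:
    def test_neutral_drift_is_a_martingale(self):
        # mean final frequency across replicate loci stays at the start
        p0 = 0.3
        mat, truth = simulate.simulate_wright_fisher_forward(
            N_diploid=50, L_sites=1_000, n_generations=25,
            sample_sizes_per_pop=[50], seed=21,
            init=np.full(1_000, p0))
        final = truth.derived_freq
        se = final.std() / np.sqrt(len(final))
        assert abs(final.mean() - p0) < 3 * se

    def test_two_isolated_demes_differentiate(self):
        mat, truth = simulate.simulate_wright_fisher_forward(
            N_diploid=[30, 30], L_sites=400, n_generations=30,
            sample_sizes_per_pop=[15, 15], seed=22,
            migration_matrix=[[1.0, 0.0], [0.0, 1.0]])
        # direct Hudson FST from simulated sample frequencies
        g1 = mat.dosage[:15]
        g2 = mat.dosage[15:]
        p1, p2 = g1.mean(axis=0) / 2, g2.mean(axis=0) / 2
        n1 = n2 = 30
        num = ((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1)
               - p2 * (1 - p2) / (n2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
        ok = den > 0
        fst = num[ok].sum() / den[ok].sum()
        assert fst > 0.05

    def test_recessive_deleterious_class_is_purged(self):
        cfg = [{"name": "neutral", "fraction": 0.5, "s": 0.0, "h": 0.5},
               {"name": "deleterious", "fraction": 0.5, "s": 0.10, "h": 0.0}]
        mat, truth = simulate.simulate_wright_fisher_forward(
            N_diploid=60, L_sites=1_000, n_generations=60,
            sample_sizes_per_pop=[60], seed=23, selection_config=cfg)
        neu = truth.derived_freq[truth.site_class == "neutral"]
        dele = truth.derived_freq[truth.site_class == "deleterious"]
        assert dele.mean() < neu.mean()

    def test_allele_counts_bounded_and_deterministic(self):
        a, ta = simulate.simulate_wright_fisher_forward(
            N_diploid=20, L_sites=100, n_generations=10,
            sample_sizes_per_pop=[20], seed=9)
        b, _ = simulate.simulate_wright_fisher_forward(
            N_diploid=20, L_sites=100, n_generations=10,
            sample_sizes_per_pop=[20], seed=9)
        np.testing.assert_array_equal(a.dosage, b.dosage)
        assert a.dosage.min() >= 0 and a.dosage.max() <= 2
        assert np.all(ta.derived_freq >= 0) and np.all(ta.derived_freq <= 1)

    def test_bad_migration_rows_rejected(self):
        with pytest.raises(ParameterError):
            simulate.simulate_wright_fisher_forward(
                N_diploid=[10, 10], L_sites=10, n_generations=1,
                sample_sizes_per_pop=[5, 5], seed=0,
                migration_matrix=[[0.0, 1.2], [0.0, 1.0]])


class TestAnnotations:
    def test_deleterious_fraction_matches_mixture_mass(self, rng):
        from conftest import make_matrix
        mat = make_matrix(rng.integers(0, 3, size=(4, 5_000)),
                          pos=np.arange(5_000) * 10)
        ann = simulate.attach_annotations(
            mat, {"synonymous": 0.6, "nonsynonymous": 0.4},
            {"deleterious_mass": 0.3}, seed=31)
        nonsyn = ann.klass == "nonsynonymous"
        frac = (ann.score[nonsyn] < 0.05).mean()
        n = nonsyn.sum()
        assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)

    def test_all_synonymous_config_has_no_scores(self, rng):
        from conftest import make_matrix
        mat = make_matrix(rng.integers(0, 3, size=(2, 200)))
        ann = simulate.attach_annotations(mat, {"synonymous": 1.0}, seed=1)
        assert np.all(np.isnan(ann.score))

    def test_seeded_determinism(self, rng):
        from conftest import make_matrix
        mat = make_matrix(rng.integers(0, 3, size=(2, 300)))
        a = simulate.attach_annotations(mat, {"synonymous": 0.5,
                                              "nonsynonymous": 0.5}, seed=7)
        b = simulate.attach_annotations(mat, {"synonymous": 0.5,
                                              "nonsynonymous": 0.5}, seed=7)
        assert a.klass.tolist() == b.klass.tolist()
        np.testing.assert_array_equal(
            np.nan_to_num(a.score), np.nan_to_num(b.score))


class TestOutgroupEvolution:
    def _tree(self, tmp_path, text):
        p = tmp_path / "t.nwk"
        p.write_text(text)
        from consgen.io import read_tree
        return read_tree(p)

    def test_zero_branch_lengths_copy_the_root(self, tmp_path):
        tree = self._tree(tmp_path, "((A:0.0,B:0.0):0.0,C:0.0);")
        root = np.array(list("ACGTACGT"), dtype=object)
        states = simulate.simulate_outgroup_alignment(tree, root, seed=2)
        for leaf in "ABC":
            assert states[leaf].tolist() == root.tolist()

    def test_saturated_branches_uniformize_states(self, tmp_path):
        tree = self._tree(tmp_path, "(A:5.0,B:5.0);")
        root = np.array(["A"] * 10_000, dtype=object)
        states = simulate.simulate_outgroup_alignment(tree, root, seed=3)
        counts = [np.sum(states["A"] == b) for b in "ACGT"]
        assert chisquare(counts).pvalue > 0.01

    def test_seeded_determinism(self, tmp_path):
        tree = self._tree(tmp_path, "(A:0.3,B:0.7);")
        root = np.array(["G"] * 500, dtype=object)
        a = simulate.simulate_outgroup_alignment(tree, root, seed=4)
        b = simulate.simulate_outgroup_alignment(tree, root, seed=4)
        assert a["A"].tolist() == b["A"].tolist()
        assert a["B"].tolist() == b["B"].tolist()
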