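"""Pruning likelihood and marginal posteriors against exhaustive
enumeration, the confidence-threshold calling rule, and polarization."""

import itertools

import numpy as np
import pytest
from Bio import Phylo
from io import StringIO

from consgen import ancestral, simulate
from consgen.ancestral import jc_transition
from consgen.core import FormatError
from conftest import make_matrix

BASES = "ACGT"


def read_newick(text):
    return Phylo.read(StringIO(text), "newick")


def enumerate_likelihood_and_posterior(tree, leaf_states, target):
    """Brute force: sum over all joint internal-state assignments."""
    internals = [c for c in tree.find_clades() if not c.is_terminal()]
    parent = {}
    for c in tree.find_clades():
        for ch in c.clades:
            parent[ch] = c
    site_count = len(next(iter(leaf_states.values())))
    totals = np.zeros(site_count)
    post = np.zeros((site_count, 4))
    for s in range(site_count):
        total = 0.0
        by_state = np.zeros(4)
        for assign in itertools.product(range(4), repeat=len(internals)):
            state = dict(zip(internals, assign))
            p = 0.25  # uniform prior at the root
            ok = True
            for c in tree.find_clades():
                if c is tree.root:
                    continue
                P = jc_transition(c.branch_length or 0.0)
                if c.is_terminal():
                    obs = leaf_states[c.name][s]
                    if obs == "N":
                        child_prob = 1.0
                    else:
                        child_prob = P[state[parent[c]], BASES.index(obs)]
                else:
                    child_prob = P[state[parent[c]], state[c]]
                p *= child_prob
                if p == 0.0:
                    ok = False
            total += p
            by_state[state[target]] += p
        totals[s] = total
        post[s] = by_state / total
    return totals, post


class TestSiteLikelihood:
    def test_zero_lengths_unanimous_leaves(self):
        tree = read_newick("((A:0,B:0):0,C:0);")
        states = {k: np.array(["A", "A"], dtype=object) for k in "ABC"}
        _, total = ancestral.site_likelihood(tree, states)
        # only the root state A contributes: prior 0.25, all transitions 1
        assert np.allclose(total, 0.25)

    def test_unknown_leaf_label_raises(self):
        tree = read_newick("(A:0.1,B:0.1);")
        with pytest.raises(FormatError):
            ancestral.site_likelihood(
                tree, {"A": np.array(["A"], dtype=object),
                       "Z": np.array(["C"], dtype=object)})

    def test_four_taxon_likelihood_matches_enumeration(self, rng):
        tree = read_newick("((A:0.21,B:0.08):0.11,(C:0.3,D:0.05):0.2);")
        leaves = {n: rng.choice(list("ACGTN"), size=6).astype(object)
                  for n in "ABCD"}
        _, total = ancestral.site_likelihood(tree, leaves)
        internals = [c for c in tree.find_clades() if not c.is_terminal()]
        brute, _ = enumerate_likelihood_and_posterior(tree, leaves,
                                                      internals[0])
        assert np.allclose(total, brute, atol=1e-12, rtol=1e-10)


class TestMarginalPosterior:
    def test_unanimous_zero_length_posterior_is_delta(self):
        tree = read_newick("((A:0,B:0):0,C:0);")
        states = {k: np.array(["G"], dtype=object) for k in "ABC"}
        post = ancestral.marginal_posterior(tree, states)
        assert post[0, BASES.index("G")] == pytest.approx(1.0)

    def test_saturated_branches_approach_uniform(self):
        tree = read_newick("(A:40.0,B:40.0);")
        states = {"A": np.array(["A"], dtype=object),
                  "B": np.array(["T"], dtype=object)}
        post = ancestral.marginal_posterior(tree, states)
        assert np.allclose(post[0], 0.25, atol=1e-6)

    @pytest.mark.parametrize("newick", [
        "((A:0.1,B:0.3):0.2,C:0.4);",
        "((A:0.15,B:0.05):0.1,(C:0.2,D:0.3):0.25);",
        "(((A:0.1,B:0.1):0.1,C:0.2):0.1,(D:0.3,E:0.1):0.2);",
        "((A:0.02,(B:0.4,C:0.1):0.08):0.3,((D:0.2,E:0.05):0.1,F:0.25):0.15);",
    ])
    def test_matches_enumeration_on_random_states(self, newick, rng):
        tree = read_newick(newick)
        names = [c.name for c in tree.get_terminals()]
        leaves = {n: rng.choice(list("ACGTN"), size=5).astype(object)
                  for n in names}
        for target in [c for c in tree.find_clades() if not c.is_terminal()]:
            post = ancestral.marginal_posterior(tree, leaves, node=target)
            _, brute = enumerate_likelihood_and_posterior(tree, leaves,
                                                          target)
            assert np.allclose(post, brute, atol=1e-12, rtol=1e-9)
            assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)


class TestCallAncestral:
    def test_threshold_rule(self):
        post = np.array([[0.96, 0.02, 0.01, 0.01],
                         [0.94, 0.06, 0.0, 0.0],
                         [0.5, 0.5, 0.0, 0.0]])
        calls = ancestral.call_ancestral(post)
        assert calls.call.tolist() == ["A", "N", "N"]
        assert calls.high_confidence.tolist() == [True, False, False]


class TestPolarize:
    def test_ancestral_ref_is_identity(self):
        m = make_matrix([[0, 1], [2, 1]])
        out, daf, stats = ancestral.polarize(m, np.array(["A", "A"],
                                                         dtype=object))
        np.testing.assert_array_equal(out.dosage, m.dosage)
        assert stats["retained"] == 2
        assert daf.tolist() == [0.5, 0.5]

    def test_ancestral_alt_flips_dosage(self):
        m = make_matrix([[2], [0]])
        out, daf, _ = ancestral.polarize(m, np.array(["T"], dtype=object))
        assert out.dosage[:, 0].tolist() == [0, 2]
        assert out.polarized

    def test_unpolarized_and_mismatching_sites_excluded(self):
        m = make_matrix([[1, 1, 1]], ref=["A", "A", "A"],
                        alt=["T", "T", "T"],
                        ancestral=["N", "N", "N"])
        out, _, stats = ancestral.polarize(
            m, np.array(["N", "G", "A"], dtype=object))
        assert out.n_sites == 1
        assert stats["unpolarized_N"] == 1 and stats["mismatched"] == 1

    def test_polarize_twice_is_identity_on_retained_sites(self, rng):
        dos = rng.integers(-1, 3, size=(6, 30))
        anc = rng.choice(["A", "T"], size=30).astype(object)
        m = make_matrix(dos)
        once, _, _ = ancestral.polarize(m, anc)
        twice, _, _ = ancestral.polarize(once, once.ancestral)
        np.testing.assert_array_equal(once.dosage, twice.dosage)

    def test_pipeline_recovers_simulated_truth(self, rng):
        # evolve outgroup states from the true ancestral base at each
        # site, reconstruct at the crown, polarize, compare with truth
        from consgen.core import DemographicModel
        tree = read_newick(
            "((ingroup:0.01,og1:0.05):0.03,(og2:0.08,og3:0.1):0.05);")
        model = DemographicModel([(np.inf, 5_000)])
        mat, truth = simulate.simulate_coalescent_windows(
            12, model, 5.0, n_windows=60, seed=61, window_length=2_000)
        # truth ancestral is REF ('A'); make the alignment at SNP sites
        root = truth.ancestral
        states = simulate.simulate_outgroup_alignment(tree, root,
                                                      seed=62)
        # the ingroup leaf carries the (derived-aware) major allele;
        # use per-site consensus of the sample as its observed state
        alt_count, called = mat.allele_counts()
        consensus = np.where(alt_count * 2 > called, mat.alt, mat.ref)
        states["ingroup"] = consensus.astype(object)
        crown = tree.common_ancestor(["ingroup", "og1"])
        post = ancestral.marginal_posterior(tree, states, node=crown)
        calls = ancestral.call_ancestral(post)
        hi = calls.high_confidence
        agree = calls.call[hi] == truth.ancestral[hi]
        assert hi.sum() > 100
        assert agree.mean() >= 0.95
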