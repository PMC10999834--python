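"""Ancestral-state reconstruction on a fixed rooted tree.

Implements Felsenstein's pruning recursion under Jukes-Cantor with
uniform base frequencies, marginal posteriors at any internal node via
an up-down pass, high-confidence calling at a posterior threshold, and
SNP polarization into derived-allele coding.

An empirical-Bayes marginal reconstruction at the crown node of the
ingroup clade is the standard way to orient alleles when an outgroup
alignment is available; sites whose reconstruction stays below the
confidence threshold are left unpolarized ('N') and excluded from
derived-allele analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FormatError, GenotypeMatrix, MISSING
from .simulate import BASES

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def jc_transition(t: float) -> np.ndarray:
    """Jukes-Cantor transition matrix for branch length t (subs/site)."""
    same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
    diff = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
    P = np.full((4, 4), diff)
    np.fill_diagonal(P, same)
    return P


def _leaf_partial(states: np.ndarray) -> np.ndarray:
    """(n_sites, 4) indicator partials; 'N' is uninformative (all ones)."""
    n = len(states)
    out = np.zeros((n, 4))
    for b, i in _BASE_INDEX.items():
        out[states == b, i] = 1.0
    out[states == "N"] = 1.0
    return out


def site_likelihood(tree, leaf_states: dict[str, np.ndarray]):
    """Post-order pruning pass.

    Parameters
    ----------
    tree : Bio.Phylo tree (rooted)
    leaf_states : mapping leaf name -> array of bases ('N' allowed)

    Returns
    -------
    partials : dict clade -> (n_sites, 4) conditional likelihoods
    total : (n_sites,) likelihood at the root under uniform priors
    """
    leaves = {c.name for c in tree.get_terminals()}
    missing = set(leaf_states) - leaves
    if missing:
        raise FormatError(f"leaf labels absent from tree: {sorted(missing)}")
    absent = leaves - set(leaf_states)
    if absent:
        raise FormatError(f"no states provided for leaves: {sorted(absent)}")
    n_sites = len(next(iter(leaf_states.values())))
    partials: dict = {}

    def down(clade) -> np.ndarray:
        if clade.is_terminal():
            part = _leaf_partial(np.asarray(leaf_states[clade.name],
                                            dtype=object))
        else:
            part = np.ones((n_sites, 4))
            for child in clade.clades:
                P = jc_transition(child.branch_length or 0.0)
                part = part * (down(child) @ P.T)
        partials[clade] = part
        return part

    root_part = down(tree.root)
    total = root_part @ np.full(4, 0.25)
    return partials, total


def marginal_posterior(tree, leaf_states: dict[str, np.ndarray],
                       node=None) -> np.ndarray:
    """Marginal posterior over {A,C,G,T} at ``node`` given the leaves.

    ``node`` defaults to the root.  Combines the upward (pruning)
    partials with a downward pass carrying the information outside the
    subtree; rows sum to 1.
    """
    partials, _ = site_likelihood(tree, leaf_states)
    if node is None:
        node = tree.root
    n_sites = partials[tree.root].shape[0]
    prior = np.full(4, 0.25)

    # downward messages: outside[v][s] = P(leaves outside v, state(v)=s)
    outside: dict = {tree.root: np.tile(prior, (n_sites, 1))}

    def walk(clade):
        for child in clade.clades:
            sib = np.ones((n_sites, 4))
            for other in clade.clades:
                if other is not child:
                    P = jc_transition(other.branch_length or 0.0)
                    sib = sib * (partials[other] @ P.T)
            parent_out = outside[clade] * sib
            P = jc_transition(child.branch_length or 0.0)
            outside[child] = parent_out @ P
            if not child.is_terminal():
                walk(child)

    walk(tree.root)
    if node not in outside:
        raise FormatError("node not found in tree")
    joint = outside[node] * partials[node]
    total = joint.sum(axis=1, keepdims=True)
    return joint / total


def find_mrca(tree, leaf_names):
    """MRCA clade of a set of leaf labels (the user-specified crown node)."""
    return tree.common_ancestor([{"name": n} for n in leaf_names])


@dataclass
class AncestralCalls:
    """Per-site posterior, called state ('N' when ambiguous), confidence."""

    posterior: np.ndarray   # (n_sites, 4)
    call: np.ndarray        # base or 'N'
    high_confidence: np.ndarray  # bool


def call_ancestral(posterior: np.ndarray, threshold: float = 0.95
                   ) -> AncestralCalls:
    """Argmax state when its posterior clears the threshold, else 'N'.

    Exact ties between the top two states are ambiguous and give 'N'
    regardless of the threshold.
    """
    if np.any(np.abs(posterior.sum(axis=1) - 1.0) > 1e-6):
        raise FormatError("posterior rows must sum to 1")
    order = np.argsort(posterior, axis=1)
    best = order[:, -1]
    top = posterior[np.arange(len(best)), best]
    second = posterior[np.arange(len(best)), order[:, -2]]
    tied = top == second
    confident = (top >= threshold) & ~tied
    call = np.where(confident,
                    np.array(list(BASES), dtype=object)[best], "N")
    return AncestralCalls(posterior=posterior, call=call.astype(object),
                          high_confidence=confident)


def polarize(matrix: GenotypeMatrix, ancestral: np.ndarray
             ) -> tuple[GenotypeMatrix, np.ndarray, dict]:
    """Recode dosages as derived-allele counts given per-site ancestral bases.

    Sites with ancestral 'N' or an ancestral base matching neither
    allele are excluded (counted in the returned stats).  Returns
    ``(polarized matrix, per-site DAF, stats)``.
    """
    anc = np.asarray(ancestral, dtype=object)
    if len(anc) != matrix.n_sites:
        raise FormatError("ancestral array length != n_sites")
    is_ref = anc == matrix.ref
    is_alt = anc == matrix.alt
    keep = is_ref | is_alt
    stats = {
        "input_sites": matrix.n_sites,
        "unpolarized_N": int(np.sum(anc == "N")),
        "mismatched": int(np.sum(~keep & (anc != "N"))),
        "retained": int(keep.sum()),
    }
    out = matrix.take_sites(keep)
    flip = is_alt[keep]
    d = out.dosage
    flipped = np.where(d == MISSING, MISSING, 2 - d)
    out.dosage = np.where(flip[None, :], flipped, d).astype(np.int16)
    out.ancestral = anc[keep].copy()
    # after recoding, REF/ALT labels follow ancestral/derived orientation
    ref = np.where(flip, out.alt, out.ref)
    alt = np.where(flip, out.ref, out.alt)
    out.ref, out.alt = ref.astype(object), alt.astype(object)
    out.ancestral = out.ref.copy()
    out.polarized = True
    der, called = out.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        daf = np.where(called > 0, der / np.maximum(called, 1), np.nan)
    return out, daf, stats
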