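"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import phylodissect as pdx
from phylodissect.seqio import AMINO_ACIDS, MISSING_CODE, Alignment


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def tiny_alignment():
    return Alignment.from_sequences(
        [("A", "ARND"), ("B", "ARNE"), ("C", "ARKE")]
    )


@pytest.fixture
def poisson_uniform():
    return pdx.build_model("poisson", frequencies="uniform")


@pytest.fixture
def lg_gamma():
    return pdx.build_model("lg", alpha=0.8, k=4)


def random_alignment(rng, n_taxa, n_cols, alphabet=AMINO_ACIDS, missing_prob=0.0):
    codes = rng.integers(0, alphabet.n_states, size=(n_taxa, n_cols)).astype(np.int8)
    if missing_prob:
        mask = rng.random(codes.shape) < missing_prob
        codes[mask] = MISSING_CODE
    taxa = [f"T{i:02d}" for i in range(n_taxa)]
    return Alignment(taxa, codes, alphabet)


def brute_force_site_loglik(aln, tree, model):
    """Exhaustive sum over all internal-state assignments (test oracle).

    Independent of the pruning engine: enumerates every assignment of
    states to internal nodes, multiplying stationary frequency at the root
    and one transition probability per branch, averaged over gamma
    categories. Only feasible for tiny trees / small alphabets.
    """
    n = model.n_states
    internals = [
        node for node in tree.preorder_node_iter() if not node.is_leaf()
    ]
    leaves = list(tree.leaf_node_iter())
    row = {t: i for i, t in enumerate(aln.taxa)}
    rates = model.category_rates
    out = []
    for col in aln.codes.T:
        site_l = 0.0
        for r in rates:
            P = {
                id(node): model.transition_matrix(node.edge.length or 0.0, r)
                for node in tree.preorder_node_iter()
                if node.parent_node is not None
            }
            for assignment in itertools.product(range(n), repeat=len(internals)):
                state = {id(node): s for node, s in zip(internals, assignment)}
                term = model.frequencies[state[id(tree.seed_node)]]
                for node in internals:
                    if node.parent_node is not None:
                        term *= P[id(node)][state[id(node.parent_node)], state[id(node)]]
                for leaf in leaves:
                    s = col[row[leaf.taxon.label]]
                    if s == MISSING_CODE:
                        continue
                    term *= P[id(leaf)][state[id(leaf.parent_node)], s]
                site_l += term / len(rates)
        out.append(np.log(site_l))
    return np.array(out)
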