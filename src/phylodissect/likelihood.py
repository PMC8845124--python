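"""Felsenstein-pruning likelihood engine for amino-acid (or recoded) data.

Per-site log-likelihoods on a fixed tree under a reversible model with
discrete-gamma rate variation, and branch-length optimisation on a fixed
topology. Unique site patterns are collapsed before pruning; numerical
underflow is handled by per-node partial rescaling with accumulated log
scalers.

Conditional likelihoods follow the usual inside/outside decomposition: for a
node ``c`` with parent ``p``, ``F_c(i)`` is the probability of the data below
``c`` given state ``i`` at ``c``, and ``H_c(i)`` the joint probability of all
data outside ``c``'s subtree and state ``i`` at ``p`` (stationary frequencies
enter at the root). The total likelihood is then
``sum_ij H_c(i) P_ij(t_c) F_c(j)`` for any branch, which makes each branch a
cheap univariate problem for Brent's method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .errors import UnknownTaxonError
from .models import SubstitutionModel
from .seqio import MISSING_CODE, Alignment

logger = logging.getLogger(__name__)

DEFAULT_MIN_BRANCH = 1e-8
DEFAULT_MAX_BRANCH = 20.0


@dataclass
class SiteLikelihoods:
    """Per-column log-likelihoods; ``total`` is their sum."""

    per_site: np.ndarray

    @property
    def total(self) -> float:
        return float(self.per_site.sum())


class _Engine:
    """Array-indexed view of a dendropy tree bound to one alignment + model."""

    def __init__(self, aln: Alignment, tree: dendropy.Tree, model: SubstitutionModel):
        self.model = model
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        self.node_of = nodes
        index = {id(n): i for i, n in enumerate(nodes)}
        self.root = index[id(tree.seed_node)]
        self.children: list[list[int]] = [[] for _ in nodes]
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.lengths = np.zeros(self.n_nodes)
        for i, n in enumerate(nodes):
            for ch in n.child_nodes():
                j = index[id(ch)]
                self.children[i].append(j)
                self.parent[j] = i
            if n.edge.length is not None and i != self.root:
                if n.edge.length < 0:
                    raise ValueError("negative branch length")
                self.lengths[i] = n.edge.length
        self.is_leaf = np.array([not self.children[i] for i in range(self.n_nodes)])

        # site-pattern compression
        row_of = {t: r for r, t in enumerate(aln.taxa)}
        leaf_rows = {}
        for i, n in enumerate(nodes):
            if self.is_leaf[i]:
                label = n.taxon.label
                if label not in row_of:
                    raise UnknownTaxonError(label)
                leaf_rows[i] = row_of[label]
        used = [leaf_rows[i] for i in sorted(leaf_rows)]
        sub = aln.codes[used]
        patterns, inverse, counts = np.unique(
            sub.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns.T  # (n_used_taxa, n_patterns)
        self.inverse = inverse
        self.counts = counts.astype(float)
        self.pattern_row = {
            i: k for k, i in enumerate(sorted(leaf_rows))
        }  # node -> row within self.patterns
        self.n_patterns = self.patterns.shape[1]

    # -- pruning ---------------------------------------------------------

    def _leaf_contrib(self, node: int, P: np.ndarray) -> np.ndarray:
        """(k, m, n) contribution P(t)[:, state] of a leaf; missing -> 1."""
        states = self.patterns[self.pattern_row[node]]
        contrib = P[:, :, np.clip(states, 0, None)].transpose(0, 2, 1).copy()
        contrib[:, states == MISSING_CODE, :] = 1.0
        return contrib

    def _recompute_node(self, i: int) -> None:
        """Refresh F[i], its log scaler, and the edge contributions of its
        children, from current branch lengths and child partials."""
        k = len(self.model.category_rates)
        m, n = self.n_patterns, self.model.n_states
        prod = np.ones((k, m, n))
        sc = np.zeros(m)
        for c in self.children[i]:
            P = self.model.transition_matrices(self.lengths[c])
            if self.is_leaf[c]:
                contrib = self._leaf_contrib(c, P)
            else:
                # contrib[k,m,i] = sum_j P[k,i,j] F[c][k,m,j]
                contrib = np.matmul(self.F[c], P.transpose(0, 2, 1))
                sc += self.logsc[c]
            self.edge[c] = contrib
            prod *= contrib
        scale = prod.max(axis=(0, 2))
        scale[scale <= 0] = 1.0
        prod /= scale[None, :, None]
        self.F[i] = prod
        self.logsc[i] = sc + np.log(scale)

    def init_partials(self) -> None:
        """Full postorder computation of inside partials and edge contributions."""
        k = len(self.model.category_rates)
        m = self.n_patterns
        self.F: list[np.ndarray | None] = [None] * self.n_nodes
        self.logsc = [np.zeros(m) for _ in range(self.n_nodes)]
        self.edge: list[np.ndarray | None] = [None] * self.n_nodes
        self._dirty: set[int] = set()
        for i in range(self.n_nodes):  # postorder by construction
            if not self.is_leaf[i]:
                self._recompute_node(i)

    def set_length(self, c: int, t: float) -> None:
        """Update one branch length, invalidating partials on the root path."""
        self.lengths[c] = t
        p = self.parent[c]
        while p != -1 and p not in self._dirty:
            self._dirty.add(p)
            p = self.parent[p]

    def refresh(self) -> None:
        for i in range(self.n_nodes):
            if i in self._dirty:
                self._recompute_node(i)
        self._dirty.clear()

    def pattern_loglik(self) -> np.ndarray:
        pi = self.model.frequencies
        root = self.F[self.root]
        k = root.shape[0]
        L = np.einsum("kmi,i->m", root, pi) / k
        return np.log(L) + self.logsc[self.root]

    def site_loglik(self) -> np.ndarray:
        self.init_partials()
        return self.pattern_loglik()[self.inverse]

    def total_loglik(self) -> float:
        if not hasattr(self, "F"):
            self.init_partials()
        else:
            self.refresh()
        return float(self.pattern_loglik() @ self.counts)

    # -- outside partials -------------------------------------------------

    def _outside(self, c: int):
        """H_c (k, m, n) over states at parent(c), with its log scaler."""
        k = self.F[self.root].shape[0]
        m, n = self.n_patterns, self.model.n_states
        path = []
        node = c
        while node != self.root:
            path.append(node)
            node = self.parent[node]
        path.reverse()  # root-side first; entries are the "next child" at each step
        pi = self.model.frequencies
        H = np.broadcast_to(pi, (k, m, n)).copy()
        sc = np.zeros(m)
        p = self.root
        for q in path:
            for s in self.children[p]:
                if s == q:
                    continue
                H = H * self.edge[s]
                if not self.is_leaf[s]:
                    sc += self.logsc[s]
            scale = H.max(axis=(0, 2))
            scale[scale <= 0] = 1.0
            H /= scale[None, :, None]
            sc += np.log(scale)
            if q != c:  # descend through q's own branch
                P = self.model.transition_matrices(self.lengths[q])
                # H_new[k,m,j] = sum_i H[k,m,i] P[k,i,j]
                H = np.matmul(H, P)
            p = q
        return H, sc

    def edge_loglik_fn(self, c: int):
        """Return f(t) = total lnL as a function of branch c's length.

        Partials must be fresh (call :meth:`refresh` after length updates).
        """
        H, scH = self._outside(c)
        if self.is_leaf[c]:
            scF = 0.0
        else:
            Fc = self.F[c]
            scF = self.logsc[c]
        k = H.shape[0]
        const = scH + scF

        def fn(t: float) -> float:
            P = self.model.transition_matrices(t)
            if self.is_leaf[c]:
                contrib = self._leaf_contrib(c, P)
            else:
                contrib = np.matmul(Fc, P.transpose(0, 2, 1))
            L = np.einsum("kmi,kmi->m", H, contrib) / k
            return float((np.log(L) + const) @ self.counts)

        return fn

    def write_lengths(self, tree: dendropy.Tree) -> None:
        nodes = list(tree.postorder_node_iter())
        for i, n in enumerate(nodes):
            if i != self.root:
                n.edge.length = float(self.lengths[i])


def site_loglikelihoods(
    aln: Alignment, tree: dendropy.Tree, model: SubstitutionModel
) -> SiteLikelihoods:
    """Per-column log-likelihood of the alignment on the tree.

    Tree leaves must be a subset of the alignment's taxa; only rows for
    leaves present in the tree contribute. Gap/missing cells contribute
    all-ones partials (no information).
    """
    return SiteLikelihoods(_Engine(aln, tree, model).site_loglik())


def total_loglikelihood(
    aln: Alignment, tree: dendropy.Tree, model: SubstitutionModel
) -> float:
    return _Engine(aln, tree, model).total_loglik()


def optimize_branch_lengths(
    aln: Alignment,
    topology: dendropy.Tree,
    model: SubstitutionModel,
    *,
    min_branch: float = DEFAULT_MIN_BRANCH,
    max_branch: float = DEFAULT_MAX_BRANCH,
    tol: float = 1e-6,
    max_sweeps: int = 50,
    initial_length: float = 0.1,
    xatol: float = 1e-8,
) -> tuple[dendropy.Tree, float]:
    """Maximum-likelihood branch lengths on a fixed topology.

    Coordinate-wise Brent optimisation of each branch within
    ``[min_branch, max_branch]``, sweeping over branches until the total
    log-likelihood improves by less than ``tol`` (or ``max_sweeps`` is hit,
    which logs a warning and returns the best lengths found). Branches with
    no starting length (or zero) start at ``initial_length``.

    Returns a new tree (the input is not modified) and the final lnL.
    """
    work = topology.clone(depth=1)
    eng = _Engine(aln, work, model)
    start = eng.lengths.copy()
    start[start <= 0] = initial_length
    start = np.clip(start, min_branch, max_branch)
    start[eng.root] = 0.0
    eng.lengths = start

    eng.init_partials()
    best = eng.total_loglik()
    branches = [i for i in range(eng.n_nodes) if i != eng.root]
    converged = False
    for _ in range(max_sweeps):
        prev_lengths = eng.lengths.copy()
        for c in branches:
            eng.refresh()
            fn = eng.edge_loglik_fn(c)
            res = minimize_scalar(
                lambda t: -fn(t),
                bounds=(min_branch, max_branch),
                method="bounded",
                options={"xatol": xatol},
            )
            if -res.fun >= fn(eng.lengths[c]):
                eng.set_length(c, float(res.x))
        now = eng.total_loglik()
        if now < best - 1e-9:  # safeguard; Brent acceptance should prevent this
            logger.warning("sweep decreased lnL; keeping previous lengths")
            eng.lengths = prev_lengths
            break
        gain, best = now - best, max(now, best)
        if gain < tol:
            converged = True
            break
    if not converged:
        logger.warning("branch-length optimisation hit max_sweeps=%d", max_sweeps)
    eng.write_lengths(work)
    return work, best
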