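"""Per-locus substitution-saturation regression and slow-locus selection.

A saturation plot regresses uncorrected pairwise p-distances on patristic
(tree) distances; a slope near one means observed differences track the
inferred amount of change, while a flattened slope indicates multiple hits
have erased signal. Loci with high slope and tight fit (defaults: slope
>= 0.4, r^2 >= 0.95) are retained as the slowly evolving subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats

from .errors import InsufficientDataError
from .seqio import MISSING_CODE, Alignment

logger = logging.getLogger(__name__)

DEFAULT_SLOPE_MIN = 0.4
DEFAULT_R2_MIN = 0.95
#: pairs sharing fewer non-missing columns than this are excluded
MIN_SHARED_COLUMNS = 20


@dataclass(frozen=True)
class SaturationStats:
    """OLS summary of one locus's saturation plot."""

    name: str
    slope: float
    r2: float
    n_pairs: int


def p_distance_matrix(
    aln: Alignment, min_shared: int = MIN_SHARED_COLUMNS
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise uncorrected p-distances with pairwise deletion.

    Returns ``(distances, usable)`` where ``usable[i, j]`` is False for
    pairs sharing fewer than ``min_shared`` non-missing columns (their
    distance is reported as NaN and they are excluded from regression).
    """
    if aln.n_taxa < 2:
        raise InsufficientDataError("need at least two taxa")
    present = aln.codes != MISSING_CODE
    n = aln.n_taxa
    dist = np.zeros((n, n))
    usable = np.ones((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            shared = int(both.sum())
            if shared < min_shared:
                dist[i, j] = dist[j, i] = np.nan
                usable[i, j] = usable[j, i] = False
                continue
            diff = int((aln.codes[i, both] != aln.codes[j, both]).sum())
            dist[i, j] = dist[j, i] = diff / shared
    return dist, usable


def patristic_matrix(
    tree: dendropy.Tree, taxa: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """All-pairs path-length distances between leaves.

    Returns the matrix and the taxon order used (``taxa`` if given,
    otherwise the tree's leaf order). Missing branch lengths are an error.
    """
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has a missing branch length")
    pdm = tree.phylogenetic_distance_matrix()
    labels = taxa if taxa is not None else [
        leaf.taxon.label for leaf in tree.leaf_node_iter()
    ]
    lookup = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(lookup[labels[i]], lookup[labels[j]])
            out[i, j] = out[j, i] = d
    return out, labels


def saturation_regression(
    p_dist: np.ndarray,
    tree_dist: np.ndarray,
    usable: np.ndarray | None = None,
    name: str = "",
) -> SaturationStats:
    """OLS of p-distance on patristic distance over the upper triangle.

    Fits ``y = a + b x`` with a free intercept; ``r2`` is the squared
    Pearson correlation. Requires at least three usable pairs.
    """
    if p_dist.shape != tree_dist.shape:
        raise ValueError("matrices must share a taxon set")
    n = p_dist.shape[0]
    iu = np.triu_indices(n, k=1)
    x = tree_dist[iu]
    y = p_dist[iu]
    mask = ~np.isnan(y)
    if usable is not None:
        mask &= usable[iu]
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise InsufficientDataError(f"only {x.size} usable pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        # degenerate: no variance on one axis; slope 0 by convention
        return SaturationStats(name, 0.0, 0.0, int(x.size))
    fit = stats.linregress(x, y)
    return SaturationStats(name, float(fit.slope), float(fit.rvalue**2), int(x.size))


def locus_saturation(
    aln: Alignment, tree: dendropy.Tree, name: str = ""
) -> SaturationStats:
    """Saturation regression of one locus against a tree with branch lengths.

    The tree is restricted to the locus's taxa before computing patristic
    distances.
    """
    taxa = [t for t in aln.taxa]
    sub = tree.extract_tree_with_taxa_labels(taxa)
    p_dist, usable = p_distance_matrix(aln)
    t_dist, _ = patristic_matrix(sub, taxa=taxa)
    return saturation_regression(p_dist, t_dist, usable, name=name)


def select_slow_loci(
    stats_list: list[SaturationStats],
    slope_min: float = DEFAULT_SLOPE_MIN,
    r2_min: float = DEFAULT_R2_MIN,
) -> list[str]:
    """Names of loci with slope >= slope_min and r^2 >= r2_min, in order."""
    return [s.name for s in stats_list if s.slope >= slope_min and s.r2 >= r2_min]
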