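"""Dissection of phylogenetic signal between two competing topologies.

Gene-wise (dGLS) and site-wise (dSLS) log-likelihood support: a locus or
site with dGLS/dSLS > 0 favours hypothesis T1, < 0 favours T2. Support-class
proportions, per-class comparison of locus properties linked to systematic
error (length, informative sites, missing data, rate, saturation), and gene
and site concordance factors for the branches of a reference topology.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .likelihood import optimize_branch_lengths, site_loglikelihoods
from .matrixops import count_informative_sites, missing_fraction
from .models import SubstitutionModel
from .saturation import locus_saturation
from .seqio import MISSING_CODE, Alignment, LocusSet

logger = logging.getLogger(__name__)


def _restrict(tree: dendropy.Tree, taxa: list[str]) -> dendropy.Tree:
    present = {l.taxon.label for l in tree.leaf_node_iter()}
    keep = [t for t in taxa if t in present]
    if len(keep) < 3:
        raise InsufficientDataError("fewer than 3 shared taxa after restriction")
    return tree.extract_tree_with_taxa_labels(keep)


def delta_gls(
    locus: Alignment,
    t1: dendropy.Tree,
    t2: dendropy.Tree,
    model: SubstitutionModel,
    mode: str = "reoptimize",
    **opt_options,
) -> float:
    """lnL(locus | T1) - lnL(locus | T2); positive values support T1.

    Both hypothesis trees are pruned to the locus's taxa first and must then
    share that leaf set. In ``reoptimize`` mode branch lengths are fitted by
    maximum likelihood per topology (the meaningful comparison for
    constrained-vs-unconstrained hypotheses); ``fixed`` mode scores the
    given branch lengths as-is. Extra keyword arguments are passed to
    :func:`optimize_branch_lengths` (e.g. a looser ``tol`` for large
    screens where only the sign of the score matters).
    """
    r1 = _restrict(t1, locus.taxa)
    r2 = _restrict(t2, locus.taxa)
    l1 = {l.taxon.label for l in r1.leaf_node_iter()}
    l2 = {l.taxon.label for l in r2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("hypothesis trees disagree on the locus's taxa")
    if mode == "reoptimize":
        _, lnl1 = optimize_branch_lengths(locus, r1, model, **opt_options)
        _, lnl2 = optimize_branch_lengths(locus, r2, model, **opt_options)
    elif mode == "fixed":
        lnl1 = site_loglikelihoods(locus, r1, model).total
        lnl2 = site_loglikelihoods(locus, r2, model).total
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(lnl1 - lnl2)


def delta_sls(
    supermatrix: Alignment,
    t1: dendropy.Tree,
    t2: dendropy.Tree,
    model: SubstitutionModel,
    optimize: bool = True,
    **opt_options,
) -> np.ndarray:
    """Per-site lnL(T1) - lnL(T2) on the supermatrix.

    With ``optimize`` (default) branch lengths are first fitted per topology
    on the supermatrix and then held fixed, so the site scores sum exactly
    to the matrix-level dGLS under those lengths.
    """
    r1 = _restrict(t1, supermatrix.taxa)
    r2 = _restrict(t2, supermatrix.taxa)
    if optimize:
        r1, _ = optimize_branch_lengths(supermatrix, r1, model, **opt_options)
        r2, _ = optimize_branch_lengths(supermatrix, r2, model, **opt_options)
    s1 = site_loglikelihoods(supermatrix, r1, model).per_site
    s2 = site_loglikelihoods(supermatrix, r2, model).per_site
    return s1 - s2


def classify_support(
    values: np.ndarray, tie_eps: float = 0.0
) -> tuple[float, float, float]:
    """Fractions of entries supporting T1 (> eps), T2 (< -eps), and ties."""
    if tie_eps < 0:
        raise ValueError("tie_eps must be >= 0")
    values = np.asarray(values, float)
    if values.size == 0:
        raise InsufficientDataError("no support values to classify")
    p1 = float((values > tie_eps).mean())
    p2 = float((values < -tie_eps).mean())
    return p1, p2, max(0.0, float(1.0 - p1 - p2))


def support_class(value: float, tie_eps: float = 0.0) -> str:
    if value > tie_eps:
        return "T1"
    if value < -tie_eps:
        return "T2"
    return "tie"


# ---------------------------------------------------------------------------
# per-locus signal table
# ---------------------------------------------------------------------------

def build_signal_table(
    loci: LocusSet,
    t1: dendropy.Tree,
    t2: dendropy.Tree,
    model: SubstitutionModel,
    mode: str = "reoptimize",
    tie_eps: float = 0.0,
    **opt_options,
) -> pd.DataFrame:
    """Per-locus dGLS plus the covariates used to diagnose systematic bias.

    Columns: dgls, support, columns, informative_sites, missing_fraction
    (non-sampled cells relative to the full taxon set of the hypothesis
    trees, plus in-locus gaps), rate_proxy (optimised T1 tree length /
    taxon count), slope and r2 of the saturation regression against the
    optimised T1 tree. Loci with too few shared taxa are skipped with a
    warning.
    """
    n_total_taxa = sum(1 for _ in t1.leaf_node_iter())
    rows = []
    for name, aln in loci:
        try:
            r1 = _restrict(t1, aln.taxa)
            r2 = _restrict(t2, aln.taxa)
        except InsufficientDataError:
            logger.warning("locus %s skipped: too few taxa shared with trees", name)
            continue
        if mode == "reoptimize":
            opt1, lnl1 = optimize_branch_lengths(aln, r1, model, **opt_options)
            _, lnl2 = optimize_branch_lengths(aln, r2, model, **opt_options)
        else:
            opt1 = r1
            lnl1 = site_loglikelihoods(aln, r1, model).total
            lnl2 = site_loglikelihoods(aln, r2, model).total
        dgls = float(lnl1 - lnl2)
        shared = [l.taxon.label for l in opt1.leaf_node_iter()]
        sub = aln.take_taxa(shared)
        tree_len = sum(
            e.length or 0.0 for e in opt1.preorder_edge_iter()
            if e.head_node is not opt1.seed_node
        )
        try:
            sat = locus_saturation(sub, opt1, name=name)
            slope, r2v = sat.slope, sat.r2
        except InsufficientDataError:
            slope, r2v = np.nan, np.nan
        rows.append(
            {
                "locus": name,
                "dgls": dgls,
                "support": support_class(dgls, tie_eps),
                "columns": aln.n_columns,
                "informative_sites": count_informative_sites(aln),
                "missing_fraction": 1.0
                - (1.0 - missing_fraction(aln))
                * aln.n_taxa
                / n_total_taxa,
                "rate_proxy": tree_len / len(shared),
                "slope": slope,
                "r2": r2v,
            }
        )
    return pd.DataFrame(rows)


_COVARIATES = [
    "columns",
    "informative_sites",
    "missing_fraction",
    "rate_proxy",
    "slope",
    "r2",
]


def compare_gene_properties(table: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of each covariate per support class, with a rank-sum flag.

    The flag (``t1_vs_t2_p``) is the two-sided Mann-Whitney p-value
    comparing T1- against T2-supporting loci for that covariate; NaN when a
    class is missing.
    """
    if table.empty:
        raise InsufficientDataError("empty signal table")
    rows = []
    classes = [c for c in ("T1", "T2", "tie") if (table["support"] == c).any()]
    for cov in _COVARIATES:
        rec: dict[str, float | str] = {"covariate": cov}
        for cls in classes:
            vals = table.loc[table["support"] == cls, cov].dropna()
            rec[f"{cls}_median"] = float(vals.median()) if len(vals) else np.nan
            rec[f"{cls}_iqr"] = (
                float(vals.quantile(0.75) - vals.quantile(0.25)) if len(vals) else np.nan
            )
        a = table.loc[table["support"] == "T1", cov].dropna()
        b = table.loc[table["support"] == "T2", cov].dropna()
        if len(a) and len(b):
            rec["t1_vs_t2_p"] = float(
                stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            )
        else:
            rec["t1_vs_t2_p"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# concordance factors
# ---------------------------------------------------------------------------

def _unrooted_copy(tree: dendropy.Tree) -> dendropy.Tree:
    out = tree.clone(depth=1)
    out.deroot()
    return out


def _branch_groups(tree: dendropy.Tree):
    """For each internal branch: (below leafset, four surrounding leaf groups).

    Works on an unrooted (derooted) binary tree. The four groups are the two
    child subtrees below the branch and the two components on the parent
    side; a branch is only yielded when both sides hold >= 2 leaves.
    """
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        kids = node.child_nodes()
        if len(kids) != 2:
            raise ValueError("reference tree must be binary")
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        above = all_leaves - below
        if len(below) < 2 or len(above) < 2:
            continue
        g1 = frozenset(l.taxon.label for l in kids[0].leaf_iter())
        g2 = below - g1
        parent = node.parent_node
        sibs = [c for c in parent.child_nodes() if c is not node]
        g3 = frozenset(l.taxon.label for l in sibs[0].leaf_iter())
        g4 = above - g3
        if not g4 and len(sibs) > 1:
            g4 = frozenset(l.taxon.label for l in sibs[1].leaf_iter())
        if not g4:
            continue
        yield below, (g1, g2, g3, g4)


def _tree_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits as the leafset below each internal edge."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    splits = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if 2 <= len(below) <= len(all_leaves) - 2:
            splits.add(below)
            splits.add(all_leaves - below)
    return splits


def gene_concordance_factor(
    gene_trees: list[dendropy.Tree], reference: dendropy.Tree
) -> pd.DataFrame:
    """Gene concordance factor for every internal branch of the reference.

    gCF = 100 x (decisive gene trees containing the branch's bipartition,
    restricted to the gene's taxa) / (decisive gene trees). A gene tree is
    decisive for a branch when it samples at least one taxon from each of
    the four subtrees the branch separates.
    """
    if not gene_trees:
        raise InsufficientDataError("no gene trees")
    ref = _unrooted_copy(reference)
    gene_info = []
    for gt in gene_trees:
        taxa = frozenset(l.taxon.label for l in gt.leaf_node_iter())
        gene_info.append((taxa, _tree_splits(_unrooted_copy(gt))))
    rows = []
    for below, groups in _branch_groups(ref):
        n_decisive = 0
        n_concordant = 0
        for taxa, splits in gene_info:
            if any(not (g & taxa) for g in groups):
                continue
            n_decisive += 1
            restricted = below & taxa
            # decisiveness guarantees both sides of the restricted split
            # have >= 2 taxa, so it is non-trivial for the gene tree
            if restricted in splits or (taxa - restricted) in splits:
                n_concordant += 1
        rows.append(
            {
                "branch": "|".join(sorted(below)),
                "gcf": 100.0 * n_concordant / n_decisive if n_decisive else np.nan,
                "n_decisive_genes": n_decisive,
            }
        )
    return pd.DataFrame(rows)


def site_concordance_factor(
    supermatrix: Alignment,
    reference: dendropy.Tree,
    n_quartets: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Site concordance factor for every internal branch of the reference.

    For each branch, quartets are drawn with one leaf from each of the four
    surrounding subtrees (exhaustively when there are at most ``n_quartets``
    combinations, otherwise by seeded uniform sampling). A site is decisive
    for a quartet when all four residues are present and show exactly two
    states, twice each; it is concordant when the pair split matches the
    reference branch. sCF = 100 x mean over quartets of the concordant
    fraction among decisive sites.
    """
    if n_quartets < 1:
        raise ValueError("n_quartets must be >= 1")
    rng = np.random.default_rng(seed)
    ref = _unrooted_copy(reference)
    row = {t: i for i, t in enumerate(supermatrix.taxa)}
    codes = supermatrix.codes
    rows_out = []
    for below, groups in _branch_groups(ref):
        pools = [sorted(g & set(row)) for g in groups]
        if any(not p for p in pools):
            rows_out.append(
                {
                    "branch": "|".join(sorted(below)),
                    "scf": np.nan,
                    "n_quartets": 0,
                    "n_decisive_sites": 0,
                }
            )
            continue
        total = int(np.prod([len(p) for p in pools]))
        if total <= n_quartets:
            quartets = list(itertools.product(*pools))
        else:
            quartets = [
                tuple(p[rng.integers(len(p))] for p in pools)
                for _ in range(n_quartets)
            ]
        fracs = []
        decisive_total = 0
        for a, b, c, d in quartets:
            q = codes[[row[a], row[b], row[c], row[d]]]
            present = (q != MISSING_CODE).all(axis=0)
            qa, qb, qc, qd = q[:, present]
            ab = qa == qb
            cd = qc == qd
            ac = qa == qc
            bd = qb == qd
            ad = qa == qd
            bc = qb == qc
            s_ref = ab & cd & ~ac  # groups 1,2 below vs 3,4 above
            s_alt1 = ac & bd & ~ab
            s_alt2 = ad & bc & ~ab
            decisive = s_ref | s_alt1 | s_alt2
            n_dec = int(decisive.sum())
            decisive_total += n_dec
            if n_dec:
                fracs.append(s_ref.sum() / n_dec)
        rows_out.append(
            {
                "branch": "|".join(sorted(below)),
                "scf": 100.0 * float(np.mean(fracs)) if fracs else np.nan,
                "n_quartets": len(quartets),
                "n_decisive_sites": decisive_total,
            }
        )
    return pd.DataFrame(rows_out)
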