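"""Synthetic multilocus amino-acid data with controllable long-branch structure.

Generates the statistical structure a phylogenomic signal dissection
assumes: a species tree with designated fast-evolving lineages, a pair of
competing topology hypotheses differing by one subtree regraft, loci of
heterogeneous rate and length evolved under a reversible model with
discrete-gamma among-site rate variation, and per-locus taxon dropout
producing patchy occupancy. An optional "noise" class of loci (short,
fast-evolving, generated on the alternative topology) emulates loci whose
apparent signal is systematic error rather than history.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .errors import UnknownTaxonError
from .models import SubstitutionModel, build_model
from .seqio import Alignment, LocusSet, read_tree, write_tree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Free parameters of the synthetic study.

    Defaults describe a small chelicerate-like setting: a 12-taxon species
    tree, 100 loci of 100-500 columns, moderate among-site rate variation
    (gamma shape 0.8), and 20% per-taxon-per-locus dropout. Lineage rate
    multipliers mark fast-evolving ("long-branch") leaves or clades; the
    noise block controls the minority class of short, fast loci generated
    on the alternative topology.
    """

    n_taxa: int = 12
    n_loci: int = 100
    locus_length_range: tuple[int, int] = (100, 500)
    gamma_shape: float = 0.8
    lineage_rate_multipliers: Mapping[str, float] = field(default_factory=dict)
    dropout_prob: float = 0.2
    seed: int = 0
    # generator-specific knobs
    branch_scale: float = 0.1
    locus_rate_sigma: float = 0.4
    model_name: str = "lg"
    n_clades: int = 4
    noise_fraction: float = 0.0
    noise_rate_multiplier: float = 10.0
    noise_length_range: tuple[int, int] = (60, 150)

    def __post_init__(self):
        if self.n_taxa < 2 or self.n_loci < 1:
            raise ValueError("counts must be >= 2 taxa and >= 1 locus")
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if any(m <= 0 for m in self.lineage_rate_multipliers.values()):
            raise ValueError("rate multipliers must be positive")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        if not 0 <= self.noise_fraction <= 1:
            raise ValueError("noise fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def sample_species_tree(
    n_taxa: int, branch_scale: float, seed: int
) -> dendropy.Tree:
    """Random rooted binary species tree with exponential branch lengths.

    Pure-birth (Yule) topology built by uniform random joins; every branch
    length is an independent Exponential(mean=branch_scale) draw. Leaf
    labels are ``T01, T02, ...``. Deterministic for a fixed seed.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_taxa)))
    labels = [f"T{i + 1:0{width}d}" for i in range(n_taxa)]
    subtrees = [f"{lab}:{rng.exponential(branch_scale):.10f}" for lab in labels]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        right = subtrees.pop(j)
        left = subtrees.pop(i)
        if len(subtrees) == 0:
            subtrees.append(f"({left},{right})")
        else:
            length = rng.exponential(branch_scale)
            subtrees.append(f"({left},{right}):{length:.10f}")
    return read_tree(subtrees[0] + ";")


def _leaf_set(node: dendropy.Node) -> frozenset[str]:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def _mrca(tree: dendropy.Tree, taxa: frozenset[str]) -> dendropy.Node:
    node = tree.mrca(taxon_labels=list(taxa))
    if node is None:
        raise UnknownTaxonError(sorted(taxa))
    return node


def _find_clade(tree: dendropy.Tree, taxa: frozenset[str]) -> dendropy.Node:
    """MRCA of ``taxa``, required to span exactly ``taxa``."""
    node = _mrca(tree, taxa)
    if _leaf_set(node) != taxa:
        raise ValueError(f"{sorted(taxa)} is not monophyletic in this tree")
    return node


def _attach_sister(
    tree: dendropy.Tree,
    target: dendropy.Node,
    graft_newick: str,
    stem_length: float,
) -> dendropy.Tree:
    """Attach the graft (a Newick string) as sister to ``target`` in place."""
    parent = target.parent_node
    if parent is None:
        raise ValueError("cannot attach sister to the root")
    graft = dendropy.Tree.get(
        data=graft_newick if graft_newick.endswith(";") else graft_newick + ";",
        schema="newick",
        taxon_namespace=tree.taxon_namespace,
        suppress_internal_node_taxa=True,
    )
    split = (target.edge.length or 0.0) / 2.0
    new = dendropy.Node()
    parent.remove_child(target)
    parent.add_child(new)
    new.edge.length = split
    new.add_child(target)
    target.edge.length = split
    head = graft.seed_node
    new.add_child(head)
    head.edge.length = stem_length
    # re-parse so node bookkeeping (seed paths, bipartitions) is fresh
    return read_tree(write_tree(tree))


def make_competing_pair(
    base: dendropy.Tree,
    focal_taxa: Sequence[str] | frozenset[str],
    outpost_clade: Sequence[str] | frozenset[str],
) -> tuple[dendropy.Tree, dendropy.Tree]:
    """Build the nested (T1) and monophyly (T2) hypothesis topologies.

    The outpost clade is pruned from ``base`` (where the remaining focal
    taxa must be monophyletic) and regrafted in two ways: inside the clade
    spanned by the focal taxa, as sister to the first focal taxon (T1,
    "nested" hypothesis), and as sister to the whole focal clade (T2,
    "monophyly" hypothesis: the focal taxa form a clade excluding the
    outpost). The two trees share all clades disjoint from
    ``focal ∪ outpost`` and differ by this single regraft.
    """
    focal = frozenset(focal_taxa)
    outpost = frozenset(outpost_clade)
    if not focal or not outpost:
        raise ValueError("focal and outpost sets must be non-empty")
    if focal & outpost:
        raise ValueError("focal and outpost sets must be disjoint")
    leaves = frozenset(l.taxon.label for l in base.leaf_node_iter())
    if not (focal <= leaves and outpost <= leaves):
        raise UnknownTaxonError(sorted((focal | outpost) - leaves))

    # extract the outpost subtree (with branch lengths) and its stem length
    if len(outpost) == 1:
        (sole,) = outpost
        node = _find_clade(base, outpost)
        stem = node.edge.length or 0.0
        graft_inner = f"{sole}:0.0"
    else:
        node = _find_clade(base, outpost)
        stem = node.edge.length or 0.0
        sub = base.extract_tree_with_taxa_labels(list(outpost))
        graft_inner = write_tree(sub).rstrip(";").strip()
    if stem <= 0:
        stem = 1e-3

    pruned = base.extract_tree_with_taxa_labels(list(leaves - outpost))
    _find_clade(pruned, focal)  # raises if focal not monophyletic

    anchor_leaf = sorted(focal)[0]
    t1_base = pruned.clone(depth=1)
    target = _find_clade(t1_base, frozenset([anchor_leaf]))
    t1 = _attach_sister(t1_base, target, graft_inner, stem)

    t2_base = pruned.clone(depth=1)
    target = _find_clade(t2_base, focal)
    t2 = _attach_sister(t2_base, target, graft_inner, stem)
    return t1, t2


def scale_branches(
    tree: dendropy.Tree,
    multipliers: Mapping[str, float],
    clade_map: Mapping[str, str] | None = None,
) -> dendropy.Tree:
    """Multiply branch lengths of selected lineages; topology unchanged.

    Keys name either a single leaf (its terminal branch is scaled) or a
    clade from ``clade_map`` (every branch inside the clade plus its
    subtending stem is scaled). Unresolvable keys raise
    :class:`UnknownTaxonError`.
    """
    out = tree.clone(depth=1)
    leaves = {l.taxon.label: l for l in out.leaf_node_iter()}
    for key, factor in multipliers.items():
        if factor <= 0:
            raise ValueError("multipliers must be positive")
        if key in leaves:
            node = leaves[key]
            node.edge.length = (node.edge.length or 0.0) * factor
            continue
        members = None
        if clade_map is not None:
            members = frozenset(
                t for t, c in clade_map.items() if c == key and t in leaves
            )
        if not members:
            raise UnknownTaxonError(key)
        node = _find_clade(out, members)
        node.edge.length = (node.edge.length or 0.0) * factor
        for desc in node.preorder_iter():
            if desc is node:
                continue
            desc.edge.length = (desc.edge.length or 0.0) * factor
    return out


def scale_all_branches(tree: dendropy.Tree, factor: float) -> dendropy.Tree:
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * factor
    return out


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

def simulate_alignment(
    tree: dendropy.Tree,
    model: SubstitutionModel,
    n_sites: int,
    seed: int,
) -> Alignment:
    """Evolve an alignment along the tree under the model.

    Root states are drawn from the stationary frequencies; each site draws
    one of the model's discrete-gamma categories uniformly and keeps it on
    every branch; child states are sampled from ``exp(Q r t)`` row by row.
    Rows are ordered by sorted leaf label.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    rates = model.category_rates
    cat = rng.integers(len(rates), size=n_sites)
    pi = model.frequencies
    states: dict[int, np.ndarray] = {}
    root_states = rng.choice(model.n_states, size=n_sites, p=pi)
    states[id(tree.seed_node)] = root_states
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length
        if t is None or t < 0:
            raise ValueError("every branch needs a non-negative length")
        parent_states = states[id(node.parent_node)]
        P = np.stack([model.transition_matrix(t, r) for r in rates])
        probs = P[cat, parent_states, :]  # (n_sites, n_states)
        cum = np.cumsum(probs, axis=1)
        u = rng.random(n_sites)
        states[id(node)] = (u[:, None] > cum).sum(axis=1).astype(np.int8)
    rows = {
        l.taxon.label: states[id(l)] for l in tree.leaf_node_iter()
    }
    taxa = sorted(rows)
    codes = np.vstack([rows[t] for t in taxa])
    return Alignment(taxa, codes, model.alphabet)


def mask_missing(loci: LocusSet, dropout_prob: float, seed: int) -> LocusSet:
    """Remove each (locus, taxon) pair independently with the given probability.

    Dropped taxa are absent from the locus (not gap-padded), mirroring the
    occupancy structure of transcriptomic supermatrices. A locus losing all
    but one taxon is dropped entirely (and logged), since a single row is
    no longer an alignment of homologs.
    """
    if not 0 <= dropout_prob < 1:
        raise ValueError("dropout probability must be in [0, 1)")
    if dropout_prob == 0:
        return loci
    rng = np.random.default_rng(seed)
    out = LocusSet()
    for name, aln in loci:
        keep = [t for t in aln.taxa if rng.random() >= dropout_prob]
        if len(keep) < 2:
            logger.warning("locus %s lost nearly all taxa; dropped", name)
            continue
        out.add(name, aln.take_taxa(keep))
    return out


# ---------------------------------------------------------------------------
# clade assignment and full-study generation
# ---------------------------------------------------------------------------

def assign_clades(tree: dendropy.Tree, n_clades: int) -> dict[str, str]:
    """Partition the leaves into monophyletic clades by splitting subtrees.

    Starting from the root's children, the largest current subtree is split
    until ``n_clades`` groups exist; clade names are ``clade01, ...`` in
    leaf order.
    """
    groups = [c for c in tree.seed_node.child_nodes()]
    while len(groups) < n_clades:
        groups.sort(key=lambda n: -len(list(n.leaf_iter())))
        big = groups.pop(0)
        kids = big.child_nodes()
        if not kids:
            groups.append(big)
            break
        groups.extend(kids)
    ordered = sorted(groups, key=lambda n: min(l.taxon.label for l in n.leaf_iter()))
    mapping: dict[str, str] = {}
    for i, g in enumerate(ordered):
        for leaf in g.leaf_iter():
            mapping[leaf.taxon.label] = f"clade{i + 1:02d}"
    return mapping


@dataclass
class StudyData:
    """Everything one synthetic study run produces."""

    config: SimulationConfig
    species_tree: dendropy.Tree
    t1: dendropy.Tree  # generating ("nested") hypothesis
    t2: dendropy.Tree  # alternative ("monophyly") hypothesis
    loci: LocusSet
    gene_trees: dict[str, dendropy.Tree]
    clade_map: dict[str, str]
    noise_loci: list[str]
    focal_taxa: frozenset[str]
    outpost_taxa: frozenset[str]


def simulate_study(config: SimulationConfig) -> StudyData:
    """Generate a complete synthetic study under ``config``.

    Data-generating topology is T1 (outpost nested within the focal clade);
    the noise class, if any, is generated on T2 at an elevated rate and
    shorter length. Per-locus gene trees (the scaled trees the sequences
    were actually evolved on) are returned for concordance analyses.
    """
    master = np.random.default_rng(config.seed)

    def subseed() -> int:
        return int(master.integers(2**31 - 1))

    base = sample_species_tree(config.n_taxa, config.branch_scale, subseed())
    clade_map = assign_clades(base, config.n_clades)
    clades: dict[str, list[str]] = {}
    for taxon, clade in clade_map.items():
        clades.setdefault(clade, []).append(taxon)
    by_size = sorted(clades, key=lambda c: (-len(clades[c]), c))
    focal = frozenset(clades[by_size[0]])
    outpost = frozenset(clades[sorted(clades, key=lambda c: (len(clades[c]), c))[0]])
    t1, t2 = make_competing_pair(base, focal, outpost)

    sim_t1 = scale_branches(t1, config.lineage_rate_multipliers, clade_map)
    sim_t2 = scale_branches(t2, config.lineage_rate_multipliers, clade_map)

    model = build_model(
        config.model_name, frequencies="model", alpha=config.gamma_shape, k=4
    )
    rng = np.random.default_rng(subseed())
    n_noise = int(round(config.noise_fraction * config.n_loci))
    noise_idx = set(rng.choice(config.n_loci, size=n_noise, replace=False).tolist())

    loci = LocusSet()
    gene_trees: dict[str, dendropy.Tree] = {}
    noise_names = []
    width = max(3, len(str(config.n_loci)))
    for i in range(config.n_loci):
        name = f"locus{i + 1:0{width}d}"
        rate = float(np.exp(rng.normal(0.0, config.locus_rate_sigma)))
        if i in noise_idx:
            lo, hi = config.noise_length_range
            length = int(rng.integers(lo, hi + 1))
            gtree = scale_all_branches(
                sim_t2, rate * config.noise_rate_multiplier
            )
            noise_names.append(name)
        else:
            lo, hi = config.locus_length_range
            length = int(rng.integers(lo, hi + 1))
            gtree = scale_all_branches(sim_t1, rate)
        aln = simulate_alignment(gtree, model, length, subseed())
        loci.add(name, aln)
        gene_trees[name] = gtree
    loci = mask_missing(loci, config.dropout_prob, subseed())
    gene_trees = {n: gene_trees[n] for n in loci.names}
    noise_names = [n for n in noise_names if n in loci.loci]
    return StudyData(
        config=config,
        species_tree=base,
        t1=t1,
        t2=t2,
        loci=loci,
        gene_trees=gene_trees,
        clade_map=clade_map,
        noise_loci=noise_names,
        focal_taxa=focal,
        outpost_taxa=outpost,
    )
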