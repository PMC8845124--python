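"""Locus filtering, concatenation, and per-alignment diagnostics.

Implements the supermatrix bookkeeping of multilocus phylogenomics: clade
decisiveness filtering (keep only loci sampling every required clade),
concatenation with 1-based partition ranges, parsimony-informative site
counts, missing-data fractions, per-column Shannon entropy, entropy/gap
column trimming, and reduced-alphabet (SR4) recoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import UnknownTaxonError
from .seqio import MISSING_CODE, Alignment, Alphabet, LocusSet

logger = logging.getLogger(__name__)

#: SR4 four-group amino-acid recoding of Susko & Roger (2007)
#: Mol Biol Evol 24:2139-2150: groups {A,G,N,P,S,T}, {C,H,W,Y},
#: {D,E,K,Q,R}, {F,I,L,M,V}.
SR4_GROUPS: dict[str, str] = {
    "A": "A", "G": "A", "N": "A", "P": "A", "S": "A", "T": "A",
    "C": "C", "H": "C", "W": "C", "Y": "C",
    "D": "D", "E": "D", "K": "D", "Q": "D", "R": "D",
    "F": "F", "I": "F", "L": "F", "M": "F", "V": "F",
}

SR4_ALPHABET = Alphabet("ACDF")


@dataclass(frozen=True)
class RecodingScheme:
    """Total map from the 20 amino acids onto k group symbols."""

    groups: Mapping[str, str]

    def __post_init__(self):
        source = set("ARNDCQEGHILKMFPSTWYV")
        if set(self.groups) != source:
            raise ValueError("recoding must map every amino acid exactly once")

    @property
    def target_alphabet(self) -> Alphabet:
        return Alphabet("".join(sorted(set(self.groups.values()))))


SR4 = RecodingScheme(SR4_GROUPS)


# ---------------------------------------------------------------------------
# occupancy and decisiveness
# ---------------------------------------------------------------------------

def clade_occupancy(
    locus: Alignment, clades: Mapping[str, str]
) -> dict[str, int]:
    """Number of sampled taxa per clade for one locus.

    Every clade in the map is reported, with zero for clades the locus does
    not sample. Taxa absent from the map raise :class:`UnknownTaxonError`.
    """
    counts = {clade: 0 for clade in dict.fromkeys(clades.values())}
    for taxon in locus.taxa:
        if taxon not in clades:
            raise UnknownTaxonError(taxon)
        counts[clades[taxon]] += 1
    return counts


def decisiveness_filter(
    loci: LocusSet, clades: Mapping[str, str], required: Sequence[str]
) -> LocusSet:
    """Keep exactly the loci with at least one taxon in every required clade.

    Input order is preserved and the operation is idempotent.
    """
    known = set(clades.values())
    for clade in required:
        if clade not in known:
            raise ValueError(f"required clade {clade!r} not in clade map")
    kept = []
    for name, aln in loci:
        occ = clade_occupancy(aln, clades)
        if all(occ[c] >= 1 for c in required):
            kept.append(name)
    logger.info("decisiveness filter: %d of %d loci retained", len(kept), len(loci))
    return loci.subset(kept)


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------

def concatenate(loci: LocusSet) -> tuple[Alignment, list[tuple[str, int, int]]]:
    """Build the supermatrix over the union of taxa.

    Taxa absent from a locus are padded with missing ('?') across that
    locus's columns. Returned ranges are 1-based inclusive and tile the
    supermatrix in locus order.
    """
    if len(loci) == 0:
        raise ValueError("cannot concatenate an empty locus set")
    taxa = loci.all_taxa
    alphabet = next(iter(loci))[1].alphabet
    total = sum(aln.n_columns for _, aln in loci)
    codes = np.full((len(taxa), total), MISSING_CODE, dtype=np.int8)
    row = {t: i for i, t in enumerate(taxa)}
    ranges = []
    start = 0
    for name, aln in loci:
        if aln.alphabet != alphabet:
            raise ValueError("loci use different alphabets")
        end = start + aln.n_columns
        for t in aln.taxa:
            codes[row[t], start:end] = aln.row(t)
        ranges.append((name, start + 1, end))
        start = end
    return Alignment(taxa, codes, alphabet), ranges


# ---------------------------------------------------------------------------
# per-alignment diagnostics
# ---------------------------------------------------------------------------

def informative_mask(aln: Alignment) -> np.ndarray:
    """Boolean mask of parsimony-informative columns.

    A column is informative when >= 2 distinct non-missing states each occur
    in >= 2 taxa.
    """
    n_states = aln.alphabet.n_states
    mask = np.zeros(aln.n_columns, dtype=bool)
    for j, col in enumerate(aln.codes.T):
        obs = col[col != MISSING_CODE]
        if obs.size < 4:
            continue
        freq = np.bincount(obs.astype(int), minlength=n_states)
        mask[j] = (freq >= 2).sum() >= 2
    return mask


def count_informative_sites(aln: Alignment) -> int:
    """Number of parsimony-informative columns."""
    return int(informative_mask(aln).sum())


def missing_fraction(aln: Alignment) -> float:
    """Fraction of cells that are gap or missing."""
    return float((aln.codes == MISSING_CODE).mean())


def site_entropy(aln: Alignment, return_flags: bool = False):
    """Per-column Shannon entropy H = -sum p ln p over non-missing residues.

    Plug-in frequencies, natural log. Columns with fewer than two
    non-missing cells have no meaningful frequency estimate; they are
    reported as 0 and flagged uninformative when ``return_flags`` is set.
    """
    n_states = aln.alphabet.n_states
    m = aln.n_columns
    H = np.zeros(m)
    flags = np.zeros(m, dtype=bool)
    for j, col in enumerate(aln.codes.T):
        obs = col[col != MISSING_CODE]
        if obs.size < 2:
            flags[j] = True
            continue
        freq = np.bincount(obs.astype(int), minlength=n_states).astype(float)
        p = freq[freq > 0] / obs.size
        H[j] = float(-(p * np.log(p)).sum())
    if return_flags:
        return H, flags
    return H


def trim_by_entropy(
    aln: Alignment, max_entropy: float, max_gap: float
) -> Alignment:
    """Drop columns exceeding an entropy or missing-fraction threshold.

    A stand-in for heteropecillous-site removal: high-entropy and gappy
    columns are the ones most likely to violate stationary site-profile
    assumptions. Column order is preserved; removing every column returns a
    valid zero-column result with a logged warning.
    """
    H = site_entropy(aln)
    gap = (aln.codes == MISSING_CODE).mean(axis=0)
    keep = (H <= max_entropy) & (gap <= max_gap)
    if not keep.any():
        logger.warning("entropy/gap trimming removed every column")
        return Alignment(aln.taxa, np.zeros((aln.n_taxa, 0), np.int8), aln.alphabet)
    return aln.take_columns(np.flatnonzero(keep))


def recode(aln: Alignment, scheme: RecodingScheme = SR4) -> Alignment:
    """Replace each residue by its group symbol; missing cells unchanged."""
    src = aln.alphabet
    target = scheme.target_alphabet
    lut = np.empty(src.n_states, dtype=np.int8)
    for i, aa in enumerate(src.letters):
        if aa not in scheme.groups:
            raise ValueError(f"residue {aa!r} not covered by recoding scheme")
        lut[i] = target.index(scheme.groups[aa])
    codes = np.where(
        aln.codes == MISSING_CODE, MISSING_CODE, lut[np.clip(aln.codes, 0, None)]
    ).astype(np.int8)
    return Alignment(aln.taxa, codes, target)


def recode_sr4(aln: Alignment) -> Alignment:
    """SR4 four-state recoding of an amino-acid alignment."""
    return recode(aln, SR4)
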