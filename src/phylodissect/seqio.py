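"""Alignment and tree containers plus readers/writers for the standard formats.

Sequence data are held as integer-coded numpy matrices (one row per taxon);
trees are :class:`dendropy.Tree` objects throughout the package. Supported
formats: FASTA and relaxed sequential PHYLIP for alignments, plain Newick for
trees, RAxML-style partition text, and two-column tab-delimited clade maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
from Bio import AlignIO, SeqIO

logger = logging.getLogger(__name__)

#: canonical amino-acid state order used for all integer coding
AA_LETTERS = "ARNDCQEGHILKMFPSTWYV"
#: symbols treated as missing data (gap, unknown residue, missing)
MISSING_CHARS = "-X?"
#: integer code for a missing cell
MISSING_CODE = -1


class FormatError(ValueError):
    """Malformed input file (ragged alignment, duplicate labels, bad Newick)."""


@dataclass(frozen=True)
class Alphabet:
    """Ordered state alphabet for coded alignments.

    The 20 amino acids by default; a 4-letter alphabet after SR4 recoding.
    """

    letters: str

    @property
    def n_states(self) -> int:
        return len(self.letters)

    def index(self, char: str) -> int:
        return self.letters.index(char)

    def encode(self, seq: str) -> np.ndarray:
        """Integer-code a sequence string; unknown characters become missing."""
        lut = np.full(128, -2, dtype=np.int8)
        for i, c in enumerate(self.letters):
            lut[ord(c)] = i
            lut[ord(c.lower())] = i
        for c in MISSING_CHARS:
            lut[ord(c)] = MISSING_CODE
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        codes = lut[arr]
        unknown = codes == -2
        if unknown.any():
            bad = sorted({chr(b) for b in arr[unknown]})
            logger.warning("unknown characters %s mapped to missing", bad)
            codes = np.where(unknown, MISSING_CODE, codes)
        return codes.astype(np.int8)

    def decode(self, codes: np.ndarray) -> str:
        chars = np.array(list(self.letters + "?"))
        return "".join(chars[np.where(codes == MISSING_CODE, self.n_states, codes)])


AMINO_ACIDS = Alphabet(AA_LETTERS)


class Alignment:
    """A taxa x columns character matrix over a fixed alphabet.

    Parameters
    ----------
    taxa:
        Unique taxon labels, one per row.
    codes:
        ``(n_taxa, n_columns)`` int8 matrix; ``-1`` marks gap/missing cells.
    alphabet:
        State alphabet; amino acids unless the data have been recoded.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        codes: np.ndarray,
        alphabet: Alphabet = AMINO_ACIDS,
    ):
        codes = np.asarray(codes, dtype=np.int8)
        if codes.ndim != 2:
            raise FormatError("alignment matrix must be 2-dimensional")
        if len(taxa) != codes.shape[0]:
            raise FormatError("label count does not match row count")
        if len(set(taxa)) != len(taxa):
            raise FormatError("duplicate taxon labels")
        if codes.size and (codes.max() >= alphabet.n_states or codes.min() < -1):
            raise FormatError("state code outside alphabet")
        self.taxa: list[str] = list(taxa)
        self.codes = codes
        self.alphabet = alphabet
        self._index = {t: i for i, t in enumerate(self.taxa)}

    @classmethod
    def from_sequences(
        cls,
        records: Iterable[tuple[str, str]],
        alphabet: Alphabet = AMINO_ACIDS,
    ) -> "Alignment":
        taxa, rows = [], []
        for name, seq in records:
            taxa.append(name)
            rows.append(alphabet.encode(seq))
        if not taxa:
            raise FormatError("empty alignment")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        if lengths == {0}:
            raise FormatError("alignment must have at least one column")
        return cls(taxa, np.vstack(rows), alphabet)

    # -- basic properties -------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return self.codes.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.codes[self._index[taxon]]

    def sequence(self, taxon: str) -> str:
        return self.alphabet.decode(self.row(taxon))

    def items(self) -> Iterator[tuple[str, str]]:
        for t in self.taxa:
            yield t, self.sequence(t)

    # -- derived alignments ----------------------------------------------

    def take_taxa(self, taxa: Sequence[str]) -> "Alignment":
        idx = [self._index[t] for t in taxa]
        return Alignment(list(taxa), self.codes[idx], self.alphabet)

    def take_columns(self, columns: np.ndarray) -> "Alignment":
        return Alignment(self.taxa, self.codes[:, columns], self.alphabet)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Alignment)
            and self.taxa == other.taxa
            and self.alphabet == other.alphabet
            and np.array_equal(self.codes, other.codes)
        )

    def __repr__(self) -> str:
        return f"Alignment({self.n_taxa} taxa x {self.n_columns} columns)"


@dataclass
class LocusSet:
    """Ordered, named collection of per-locus alignments."""

    names: list[str] = field(default_factory=list)
    loci: dict[str, Alignment] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, Alignment]]) -> "LocusSet":
        ls = cls()
        for name, aln in pairs:
            ls.add(name, aln)
        return ls

    def add(self, name: str, aln: Alignment) -> None:
        if name in self.loci:
            raise ValueError(f"duplicate locus name {name!r}")
        self.names.append(name)
        self.loci[name] = aln

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[tuple[str, Alignment]]:
        for name in self.names:
            yield name, self.loci[name]

    def __getitem__(self, name: str) -> Alignment:
        return self.loci[name]

    def subset(self, names: Sequence[str]) -> "LocusSet":
        return LocusSet.from_pairs((n, self.loci[n]) for n in names)

    @property
    def all_taxa(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, aln in self:
            for t in aln.taxa:
                seen.setdefault(t, None)
        return list(seen)


# ---------------------------------------------------------------------------
# alignment IO
# ---------------------------------------------------------------------------

def read_alignment(
    path: str | Path,
    format: str = "fasta",
    alphabet: Alphabet = AMINO_ACIDS,
) -> Alignment:
    """Read a FASTA or relaxed sequential PHYLIP alignment.

    Lowercase residues are upcased; characters outside the alphabet map to
    missing with a logged warning. Ragged rows or duplicate labels raise
    :class:`FormatError`.
    """
    path = Path(path)
    if format == "fasta":
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise FormatError(f"no FASTA records in {path}")
        return Alignment.from_sequences(records, alphabet)
    if format == "phylip":
        try:
            msa = AlignIO.read(str(path), "phylip-relaxed")
        except ValueError as exc:
            raise FormatError(f"bad PHYLIP file {path}: {exc}") from exc
        return Alignment.from_sequences(
            ((r.id, str(r.seq)) for r in msa), alphabet
        )
    raise ValueError(f"unknown alignment format {format!r}")


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    path = Path(path)
    if format == "fasta":
        with open(path, "w") as fh:
            for name, seq in aln.items():
                fh.write(f">{name}\n{seq}\n")
    elif format == "phylip":
        with open(path, "w") as fh:
            fh.write(f" {aln.n_taxa} {aln.n_columns}\n")
            for name, seq in aln.items():
                fh.write(f"{name}  {seq}\n")
    else:
        raise ValueError(f"unknown alignment format {format!r}")


def read_locus_set(
    directory: str | Path, pattern: str = "*.fasta", format: str = "fasta"
) -> LocusSet:
    """Read every matching file in a directory as one locus (sorted by name)."""
    directory = Path(directory)
    pairs = []
    for path in sorted(directory.glob(pattern)):
        pairs.append((path.stem, read_alignment(path, format=format)))
    return LocusSet.from_pairs(pairs)


def write_locus_set(loci: LocusSet, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, aln in loci:
        p = directory / f"{name}.fasta"
        write_alignment(aln, p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# tree IO
# ---------------------------------------------------------------------------

def read_tree(newick: str) -> dendropy.Tree:
    """Parse a Newick string; branch lengths absent from the input become 0."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"bad Newick: {exc}") from exc
    tree.is_rooted = True
    defaulted = False
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            defaulted = True
    if defaulted:
        logger.warning("missing branch lengths defaulted to 0")
    return tree


def read_tree_file(path: str | Path) -> dendropy.Tree:
    return read_tree(Path(path).read_text())


def write_tree(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# partitions and clade maps
# ---------------------------------------------------------------------------

def write_partitions(
    ranges: Sequence[tuple[str, int, int]], model: str = "LG"
) -> str:
    """Emit RAxML-style partition lines from 1-based inclusive column ranges.

    Ranges must tile the matrix contiguously without overlap.
    """
    if not ranges:
        raise ValueError("no partitions given")
    expected_start = 1
    lines = []
    for name, start, end in ranges:
        if start != expected_start:
            raise ValueError(
                f"partition {name!r} starts at {start}, expected {expected_start}"
            )
        if end < start:
            raise ValueError(f"partition {name!r} has end < start")
        lines.append(f"{model}, {name} = {start}-{end}")
        expected_start = end + 1
    return "\n".join(lines) + "\n"


def read_clade_map(path: str | Path) -> dict[str, str]:
    """Read a two-column tab-delimited taxon -> clade table."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FormatError(f"clade map line {lineno}: expected 2 columns")
        taxon, clade = parts
        if taxon in mapping:
            raise FormatError(f"taxon {taxon!r} mapped twice")
        mapping[taxon] = clade
    return mapping


def write_clade_map(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, clade in mapping.items():
            fh.write(f"{taxon}\t{clade}\n")
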