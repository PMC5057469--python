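"""Nucleotide alignments with optional gene partitions.

The alignment is a taxa x sites character matrix over the DNA alphabet
(A, C, G, T, the IUPAC ambiguity codes, and ``-`` for gaps), stored
upper-case.  A parallel bitmask encoding (A=1, C=2, G=4, T=8, ambiguity
codes as unions, gap/N as the full set) backs the likelihood and
parsimony engines: the mask of a character is exactly the set of
unambiguous states it is compatible with.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# Bitmask encoding: one bit per unambiguous base, order A, C, G, T.
_CHAR_TO_MASK = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "M": 3, "R": 5, "W": 9, "S": 6, "Y": 10, "K": 12,
    "V": 7, "H": 11, "D": 13, "B": 14,
    "N": 15, "-": 15,
}
_MASK_TABLE = np.zeros(256, dtype=np.uint8)
_VALID = np.zeros(256, dtype=bool)
for _c, _m in _CHAR_TO_MASK.items():
    for _b in (ord(_c), ord(_c.lower())):
        _MASK_TABLE[_b] = _m
        _VALID[_b] = True

#: Characters with exactly one state bit set.
UNAMBIGUOUS = ("A", "C", "G", "T")


@dataclass(frozen=True)
class GenePartition:
    """A gene's column interval in a concatenated alignment, 0-based half-open."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"partition {self.name!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class Alignment:
    """A multiple sequence alignment over the DNA alphabet.

    Parameters
    ----------
    taxa:
        Ordered unique sequence labels.
    matrix:
        2-D array (or nested sequence) of single characters, one row per
        taxon.  Stored upper-case; every character must be A/C/G/T, an
        IUPAC ambiguity code, or ``-``.
    partitions:
        Optional non-overlapping gene partitions covering column intervals.
    """

    def __init__(self, taxa, matrix, partitions=None):
        self.taxa = list(taxa)
        if len(self.taxa) < 2:
            raise ValueError("alignment needs at least 2 taxa")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon labels: {dupes}")
        mat = np.asarray(matrix)
        if mat.dtype.kind not in ("U", "S"):
            raise TypeError("matrix must contain single characters")
        mat = np.char.upper(mat.astype("U1"))
        if mat.ndim != 2 or mat.shape[0] != len(self.taxa):
            raise ValueError("matrix must be 2-D with one row per taxon")
        codes = mat.view(np.uint32).reshape(mat.shape)
        bad = ~_VALID[np.minimum(codes, 255)] | (codes > 255)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"illegal character {mat[i, j]!r} for taxon {self.taxa[i]!r} at column {j}"
            )
        self.matrix = mat
        self.partitions = list(partitions) if partitions else None
        if self.partitions:
            self._check_partitions()
        self._masks = None

    def _check_partitions(self) -> None:
        names = [p.name for p in self.partitions]
        if len(set(names)) != len(names):
            raise ValueError("partition names must be unique")
        last = 0
        for p in sorted(self.partitions, key=lambda p: p.start):
            if p.start < last:
                raise ValueError(f"overlapping partitions at {p.name!r}")
            if p.end > self.n_sites:
                raise ValueError(f"partition {p.name!r} exceeds alignment length")
            last = p.end

    # ------------------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def masks(self) -> np.ndarray:
        """Bitmask encoding, shape (n_taxa, n_sites), dtype uint8."""
        if self._masks is None:
            codes = self.matrix.view(np.uint32).reshape(self.matrix.shape)
            self._masks = _MASK_TABLE[codes]
        return self._masks

    def sequence(self, taxon: str) -> str:
        return "".join(self.matrix[self.taxa.index(taxon)])

    def take_columns(self, idx, partitions=None) -> "Alignment":
        """New alignment from column indices (order preserved, repeats allowed)."""
        return Alignment(self.taxa, self.matrix[:, idx], partitions)

    def take_taxa(self, keep) -> "Alignment":
        keep = list(keep)
        rows = [self.taxa.index(t) for t in keep]
        return Alignment(keep, self.matrix[rows], self.partitions)

    def gene_slice(self, partition: GenePartition) -> "Alignment":
        return self.take_columns(np.arange(partition.start, partition.end))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.taxa == other.taxa
            and self.matrix.shape == other.matrix.shape
            and bool((self.matrix == other.matrix).all())
        )

    def __repr__(self) -> str:
        return f"Alignment({self.n_taxa} taxa x {self.n_sites} sites)"


# ----------------------------------------------------------------------
# FASTA and partition-file IO


def read_fasta(path) -> Alignment:
    """Read an aligned multi-FASTA file.

    Rejects duplicate labels, ragged rows, and illegal characters with the
    offending taxon and column named.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    taxa = [r.id for r in records]
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        detail = ", ".join(f"{r.id}:{len(r.seq)}" for r in records)
        raise ValueError(f"ragged alignment (unequal row lengths): {detail}")
    matrix = np.array([list(str(r.seq)) for r in records], dtype="U1")
    return Alignment(taxa, matrix)


def write_fasta(alignment: Alignment, path) -> None:
    records = [
        SeqRecord(Seq("".join(row)), id=taxon, description="")
        for taxon, row in zip(alignment.taxa, alignment.matrix)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_partitions(path) -> list[GenePartition]:
    """Read RAxML-style partition lines ``DNA, name = start-end``.

    On-disk coordinates are 1-based inclusive; internally 0-based half-open.
    """
    parts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                head, span = line.split("=")
                name = head.split(",")[1].strip()
                lo, hi = span.strip().split("-")
                parts.append(GenePartition(name, int(lo) - 1, int(hi)))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed partition line {line!r}") from exc
    return parts


def write_partitions(partitions, path) -> None:
    with open(path, "w") as fh:
        for p in partitions:
            fh.write(f"DNA, {p.name} = {p.start + 1}-{p.end}\n")
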