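"""Gene filtering, concatenation, and descriptive alignment statistics.

A site is *variable* when at least two distinct unambiguous bases occur in
the column, and *parsimony-informative* when at least two bases each occur
at least twice; gaps and ambiguity codes are excluded from both tallies by
default (set ``gap_as_state`` to count the gap as a fifth state).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignment import Alignment, GenePartition


def taxa_present(alignment: Alignment) -> list[str]:
    """Taxa with at least one unambiguous base (i.e. the gene is present)."""
    masks = alignment.masks()
    single = np.isin(masks, (1, 2, 4, 8))
    return [t for t, row in zip(alignment.taxa, single) if row.any()]


def filter_genes_by_taxa(gene_alignments, min_taxa: int = 7) -> list[Alignment]:
    """Retain genes present in at least ``min_taxa`` taxa (default: more
    than 6, i.e. >= 7)."""
    if min_taxa < 1:
        raise ValueError("min_taxa must be >= 1")
    return [g for g in gene_alignments if len(taxa_present(g)) >= min_taxa]


def concatenate(gene_alignments, names=None) -> Alignment:
    """Concatenate genes into one partitioned alignment.

    Taxa are the sorted union across genes; a taxon absent from a gene is
    gap-filled across that gene's block.
    """
    genes = list(gene_alignments)
    if not genes:
        raise ValueError("nothing to concatenate")
    if names is None:
        names = [f"gene{i + 1:03d}" for i in range(len(genes))]
    taxa = sorted(set().union(*(g.taxa for g in genes)))
    blocks, partitions, offset = [], [], 0
    for name, g in zip(names, genes):
        block = np.full((len(taxa), g.n_sites), "-", dtype="U1")
        for i, t in enumerate(g.taxa):
            block[taxa.index(t)] = g.matrix[i]
        blocks.append(block)
        partitions.append(GenePartition(name, offset, offset + g.n_sites))
        offset += g.n_sites
    return Alignment(taxa, np.concatenate(blocks, axis=1), partitions)


def _base_counts(alignment: Alignment, gap_as_state: bool) -> np.ndarray:
    """Per-column counts of each counted state, shape (n_states, n_sites)."""
    masks = alignment.masks()
    counts = [np.count_nonzero(masks == code, axis=0) for code in (1, 2, 4, 8)]
    if gap_as_state:
        counts.append(np.count_nonzero(alignment.matrix == "-", axis=0))
    return np.array(counts)


def count_variable_sites(alignment: Alignment, gap_as_state: bool = False) -> int:
    counts = _base_counts(alignment, gap_as_state)
    return int(((counts > 0).sum(axis=0) >= 2).sum())


def count_parsimony_informative(alignment: Alignment, gap_as_state: bool = False) -> int:
    counts = _base_counts(alignment, gap_as_state)
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


def percent(value: float, digits: int = 1, truncate: bool = False) -> float:
    """Display rounding for percentages: half-up by default, or truncation
    (both conventions occur in published tables)."""
    factor = 10**digits
    if truncate:
        return math.floor(value * factor) / factor
    return math.floor(value * factor + 0.5) / factor


@dataclass
class AlignmentSummary:
    n_taxa: int
    n_columns: int
    n_variable: int
    pct_variable: float
    n_parsimony_informative: int
    pct_informative_of_variable: float
    degenerate: bool = False  # set when there are no variable sites

    @classmethod
    def from_counts(cls, n_taxa, n_columns, n_variable, n_informative) -> "AlignmentSummary":
        if n_variable == 0:
            return cls(n_taxa, n_columns, 0, 0.0, 0, 0.0, degenerate=True)
        return cls(
            n_taxa,
            n_columns,
            n_variable,
            100.0 * n_variable / n_columns,
            n_informative,
            100.0 * n_informative / n_variable,
        )


def summarize_alignment(alignment: Alignment, gap_as_state: bool = False) -> AlignmentSummary:
    return AlignmentSummary.from_counts(
        alignment.n_taxa,
        alignment.n_sites,
        count_variable_sites(alignment, gap_as_state),
        count_parsimony_informative(alignment, gap_as_state),
    )
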