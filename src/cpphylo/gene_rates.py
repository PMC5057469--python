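"""Per-gene relative evolutionary rates on a fixed reference topology.

A gene's rate is measured by holding the concatenated-data ML topology and
model parameters fixed, re-optimizing only the branch lengths on the gene's
alignment, and dividing the resulting tree length by the concatenated
tree's length.  Values above 1 mark genes evolving faster than the
genome-wide coding average, values below 1 slower.  Genes shorter than a
minimum length are excluded from downstream rate-category analyses; the
remaining genes fall into slow / medium / fast categories at the relative
rate thresholds 0.75 and 1.5 (boundary values count as medium).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .alignment import Alignment
from .alignment_stats import concatenate, taxa_present
from .likelihood import TreeLikelihood
from .model import SubstModel
from .tree import Tree, prune_to

MIN_GENE_LENGTH = 800
RATE_LO = 0.75
RATE_HI = 1.5


@dataclass
class GeneRateRecord:
    gene: str
    length: int
    gene_tree_length: float | None
    relative_rate: float | None
    category: str | None = None
    computable: bool = True


def relative_gene_rate(
    gene_alignment: Alignment,
    concat_tree: Tree,
    model: SubstModel,
    name: str = "gene",
    min_taxa: int = 4,
) -> GeneRateRecord:
    """Relative rate of one gene against the concatenated-data tree.

    Taxa missing from the gene are pruned from the tree before branch
    lengths are re-optimized, and the denominator is the concatenated tree
    pruned to the same taxa (tree length depends on the taxon set, so both
    sides must cover the same taxa).
    """
    present = [t for t in taxa_present(gene_alignment) if t in set(concat_tree.taxa)]
    if len(present) < min_taxa:
        return GeneRateRecord(name, gene_alignment.n_sites, None, None, computable=False)
    if set(present) != set(concat_tree.taxa):
        ref = prune_to(concat_tree, present)
    else:
        ref = concat_tree
    denom = ref.tree_length()
    engine = TreeLikelihood(gene_alignment, ref, model)
    engine.optimize_branch_lengths()
    num = engine.tree.tree_length()
    return GeneRateRecord(name, gene_alignment.n_sites, num, num / denom)


def compute_gene_rates(
    concat_alignment: Alignment, concat_tree: Tree, model: SubstModel
) -> list[GeneRateRecord]:
    """Rates for every gene partition of a concatenated alignment."""
    if not concat_alignment.partitions:
        raise ValueError("concatenated alignment carries no gene partitions")
    return [
        relative_gene_rate(concat_alignment.gene_slice(p), concat_tree, model, name=p.name)
        for p in concat_alignment.partitions
    ]


def categorize_genes(
    records,
    min_length: int = MIN_GENE_LENGTH,
    lo: float = RATE_LO,
    hi: float = RATE_HI,
) -> list[GeneRateRecord]:
    """Assign slow / medium / fast / excluded in place and return the records.

    Genes below ``min_length`` are excluded; otherwise slow if rate < lo,
    fast if rate > hi, medium on the closed interval [lo, hi].  Records
    whose rate could not be computed keep category ``None``.
    """
    for r in records:
        if r.length < min_length:
            r.category = "excluded"
        elif not r.computable:
            r.category = None
        elif r.relative_rate < lo:
            r.category = "slow"
        elif r.relative_rate > hi:
            r.category = "fast"
        else:
            r.category = "medium"
    return list(records)


def concatenate_category(records, alignments, category: str) -> Alignment:
    """Concatenate the gene alignments assigned to one rate category.

    ``alignments`` maps gene name to alignment; raises if the category is
    empty.
    """
    names = [r.gene for r in records if r.category == category]
    if not names:
        raise ValueError(f"no genes in rate category {category!r}")
    return concatenate([alignments[n] for n in names], names=names)


def rates_table(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "length": [r.length for r in records],
            "tree_length": [r.gene_tree_length for r in records],
            "relative_rate": [r.relative_rate for r in records],
            "category": [r.category for r in records],
        }
    )
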