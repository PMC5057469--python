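"""Non-parametric bootstrap resampling and bipartition support.

Resampling always draws original alignment columns (not compressed
patterns) with replacement, so bootstrap weights follow the multinomial
distribution over sites exactly.
"""

from __future__ import annotations

import numpy as np

from .alignment import Alignment
from .seeding import rng_for
from .tree import Tree


def subsample_columns(alignment: Alignment, size: int, seed) -> Alignment:
    """Alignment of ``size`` columns drawn with replacement from the original."""
    if size < 1:
        raise ValueError("subsample size must be >= 1")
    rng = rng_for(seed)
    idx = rng.integers(0, alignment.n_sites, size=size)
    return alignment.take_columns(idx)


def bootstrap_alignment(alignment: Alignment, seed) -> Alignment:
    """A standard bootstrap replicate: resample to the original length."""
    return subsample_columns(alignment, alignment.n_sites, seed)


def bipartition_support(ref_tree: Tree, tree_sample) -> dict:
    """Percent of sampled trees containing each internal split of the
    reference tree.  All trees must be on the same taxon set."""
    trees = list(tree_sample)
    if not trees:
        raise ValueError("empty tree sample")
    ref_taxa = set(ref_tree.taxa)
    for t in trees:
        if set(t.taxa) != ref_taxa:
            raise ValueError("tree sample is not on the reference taxon set")
    ref_splits = ref_tree.bipartitions()
    counts = {s: 0 for s in ref_splits}
    for t in trees:
        sample_splits = t.bipartitions()
        for s in ref_splits:
            if s in sample_splits:
                counts[s] += 1
    return {s: 100.0 * c / len(trees) for s, c in counts.items()}
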