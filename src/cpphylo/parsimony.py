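"""Fitch parsimony and randomized stepwise-addition starting trees.

Character states are bitmasks (one bit per base), so the Fitch downpass is
pure bitwise arithmetic vectorized over compressed site patterns.  Trees are
binary apart from the conventional trifurcating root, where the sequential
pairwise downpass is exact (it corresponds to rooting along one of the three
incident edges).
"""

from __future__ import annotations

import numpy as np

from .alignment import Alignment
from .likelihood import compress_patterns
from .seeding import rng_for
from .tree import Node, Tree

DEFAULT_START_BL = 0.1


def _fitch(node: Node, tips, score) -> np.ndarray:
    if node.is_leaf:
        return tips[node.label]
    acc = None
    for child in node.children:
        s = _fitch(child, tips, score)
        if acc is None:
            acc = s
            continue
        inter = acc & s
        empty = inter == 0
        score += empty
        acc = np.where(empty, acc | s, inter)
    return acc


def fitch_score(tree: Tree, alignment: Alignment) -> int:
    """Minimum number of state changes on the tree (Fitch downpass)."""
    labels = [n.label for n in tree.leaves()]
    rows = [alignment.taxa.index(t) for t in labels]
    patterns, weights = compress_patterns(alignment.masks()[rows])
    tips = {t: patterns[i] for i, t in enumerate(labels)}
    score = np.zeros(weights.size, dtype=np.int64)
    _fitch(tree.root, tips, score)
    return int(np.dot(score, weights))


def parsimony_random_addition_tree(alignment: Alignment, seed) -> Tree:
    """Stepwise addition in a random taxon order, Fitch length as criterion.

    Each remaining taxon is tried on every branch of the growing tree and
    attached where the Fitch score is lowest (first minimum on ties, in
    postorder, so the result is deterministic for a fixed seed).
    """
    if alignment.n_taxa < 3:
        raise ValueError("stepwise addition needs at least 3 taxa")
    rng = rng_for(seed)
    order = list(alignment.taxa)
    rng.shuffle(order)

    patterns, weights = compress_patterns(alignment.masks())
    tips = {t: patterns[i] for i, t in enumerate(alignment.taxa)}

    root = Node()
    for label in order[:3]:
        root.add(Node(label, DEFAULT_START_BL))
    tree = Tree(root)

    def total_score() -> int:
        score = np.zeros(weights.size, dtype=np.int64)
        _fitch(tree.root, tips, score)
        return int(np.dot(score, weights))

    for label in order[3:]:
        leaf = Node(label, DEFAULT_START_BL)
        best = None
        for edge_node in tree.postorder():
            if edge_node.parent is None:
                continue
            parent = edge_node.parent
            pos = parent.children.index(edge_node)
            # splice: parent -> mid -> (edge_node, leaf)
            mid = Node(None, DEFAULT_START_BL)
            parent.children[pos] = mid
            mid.parent = parent
            mid.add(edge_node)
            mid.add(leaf)
            s = total_score()
            if best is None or s < best[0]:
                best = (s, edge_node)
            # undo
            parent.children[pos] = edge_node
            edge_node.parent = parent
        _, attach = best
        parent = attach.parent
        pos = parent.children.index(attach)
        mid = Node(None, DEFAULT_START_BL)
        parent.children[pos] = mid
        mid.parent = parent
        mid.add(attach)
        mid.add(Node(label, DEFAULT_START_BL))
    return Tree(tree.root)
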