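"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's pruning/search machinery: the
likelihood oracle enumerates all internal-state assignments per site, and
the topology oracle enumerates every unrooted tree by stepwise leaf
insertion.
"""

from __future__ import annotations

import numpy as np

from cpphylo.alignment import _CHAR_TO_MASK
from cpphylo.model import transition_probabilities
from cpphylo.tree import Node, Tree


def enumeration_loglik(alignment, tree, model) -> float:
    """Sum over all internal-node state assignments, per site and category."""
    rates = model.category_rates()
    pi = model.base_freqs
    nodes = tree.postorder()
    internal = [n for n in nodes if not n.is_leaf]
    leaves = [n for n in nodes if n.is_leaf]
    row = {n.label: alignment.taxa.index(n.label) for n in leaves}

    total = 0.0
    for col in range(alignment.n_sites):
        site_lik = 0.0
        for r in rates:
            P = {id(n): transition_probabilities(model, n.length, r) for n in nodes}
            acc = 0.0
            for assignment in np.ndindex(*(4,) * len(internal)):
                state = {id(n): s for n, s in zip(internal, assignment)}
                term = pi[state[id(tree.root)]]
                for n in nodes:
                    if n.parent is None:
                        continue
                    ps = state[id(n.parent)]
                    if n.is_leaf:
                        mask = _CHAR_TO_MASK[alignment.matrix[row[n.label], col]]
                        term *= sum(
                            P[id(n)][ps, s] for s in range(4) if (mask >> s) & 1
                        )
                    else:
                        term *= P[id(n)][ps, state[id(n)]]
                acc += term
            site_lik += acc / len(rates)
        total += np.log(site_lik)
    return float(total)


def all_unrooted_topologies(taxa, bl: float = 0.1):
    """Every unrooted binary topology over the taxa (3 leaves -> 1 tree,
    4 -> 3, 5 -> 15, ...), built by inserting leaves on every branch."""

    def build(labels):
        if len(labels) == 3:
            r = Node()
            for lab in labels:
                r.add(Node(lab, bl))
            yield Tree(r)
            return
        new, rest = labels[-1], labels[:-1]
        for t in build(rest):
            edges = [n for n in t.postorder() if n.parent is not None]
            for i in range(len(edges)):
                t2 = t.copy()
                target = [n for n in t2.postorder() if n.parent is not None][i]
                parent = target.parent
                pos = parent.children.index(target)
                mid = Node(None, bl)
                parent.children[pos] = mid
                mid.parent = parent
                mid.add(target)
                mid.add(Node(new, bl))
                yield Tree(t2.root)

    yield from build(list(taxa))
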