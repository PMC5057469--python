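"""ML tree search: NNI hill-climbing from randomized parsimony starts.

Each nearest-neighbour interchange around an internal branch is scored
lazily — only the central branch length is re-optimized, with the four
surrounding subtree partials taken from the cache — and the best improving
move per sweep is applied, followed by a full branch-length re-optimization.
The search stops when no interchange improves the log-likelihood by more
than ``tol``.
"""

from __future__ import annotations

import numpy as np

from .alignment import Alignment
from .likelihood import MAX_BL, MIN_BL, TreeLikelihood
from .model import SubstModel
from .parsimony import parsimony_random_addition_tree
from .seeding import child_seed
from .tree import Tree

from scipy.optimize import minimize_scalar


def _normalized(vec, scale):
    m = vec.max(axis=(0, 1))
    m = np.where(m > 0, m, 1.0)
    return vec / m, scale + np.log(m)


def _best_central(engine, out, osc, inner, isc, t0):
    """Optimal central-branch log-likelihood and length for a candidate."""
    curve = engine.edge_curve(out, osc, inner, isc)
    res = minimize_scalar(
        lambda t: -curve(t),
        bounds=(MIN_BL, MAX_BL),
        method="bounded",
        options={"xatol": 1e-5},
    )
    at_t0 = curve(t0)
    if -res.fun >= at_t0:
        return -res.fun, float(res.x)
    return at_t0, t0


def nni_search(
    alignment: Alignment,
    tree: Tree,
    model: SubstModel,
    tol: float = 1e-4,
    max_sweeps: int = 50,
    bl_tol: float | None = None,
) -> Tree:
    """Hill-climb by nearest-neighbour interchanges; returns the improved tree
    (with ML branch lengths) whose ``converged`` flag reflects the optimizer.

    ``bl_tol`` is the branch-length convergence tolerance (defaults to the
    NNI gain tolerance, floored at 1e-6); a coarse value speeds up
    topology-only uses such as bootstrap replicates.
    """
    if bl_tol is None:
        bl_tol = max(tol, 1e-6)
    engine = TreeLikelihood(alignment, tree, model)
    logl = engine.optimize_branch_lengths(tol=bl_tol)
    for _ in range(max_sweeps):
        engine.prepare()
        best = None  # (gain, node, swap_child_index, new_t)
        for n in engine.nodes:
            p = n.parent
            if p is None or n.is_leaf or len(n.children) != 2:
                continue
            siblings = [c for c in p.children if c is not n]
            n_other = len(siblings) + (0 if p.parent is None else 1)
            if n_other < 2:
                continue  # not an internal branch in the unrooted sense
            a, b = n.children
            ia, ib = engine._idx[id(a)], engine._idx[id(b)]
            A = np.matmul(engine._pmats(a.length), engine._down[ia])
            B = np.matmul(engine._pmats(b.length), engine._down[ib])
            Asc, Bsc = engine._dscale[ia], engine._dscale[ib]
            o = siblings[0]
            io = engine._idx[id(o)]
            O = np.matmul(engine._pmats(o.length), engine._down[io])
            Osc = engine._dscale[io]
            ip = engine._idx[id(p)]
            rest = engine._up[ip]
            rsc = engine._uscale[ip]
            for s in siblings[1:]:
                si = engine._idx[id(s)]
                rest = rest * np.matmul(engine._pmats(s.length), engine._down[si])
                rsc = rsc + engine._dscale[si]
            rest, rsc = _normalized(rest, rsc)

            side_p0, psc0 = _normalized(O * rest, Osc + rsc)
            side_n0, nsc0 = _normalized(A * B, Asc + Bsc)
            l0, _ = _best_central(engine, side_p0, psc0, side_n0, nsc0, n.length)
            for swap_idx, (keep, keep_sc, moved, moved_sc) in enumerate(
                [(B, Bsc, A, Asc), (A, Asc, B, Bsc)]
            ):
                side_n, nsc = _normalized(O * keep, Osc + keep_sc)
                side_p, psc = _normalized(moved * rest, moved_sc + rsc)
                l1, t1 = _best_central(engine, side_p, psc, side_n, nsc, n.length)
                gain = l1 - l0
                if gain > tol and (best is None or gain > best[0]):
                    best = (gain, n, swap_idx, t1)
        if best is None:
            break
        _, n, swap_idx, t1 = best
        p = n.parent
        moved = n.children[swap_idx]
        o = [c for c in p.children if c is not n][0]
        n.children[n.children.index(moved)] = o
        o.parent = n
        p.children[p.children.index(o)] = moved
        moved.parent = p
        n.length = t1
        engine.refresh_topology()
        logl = engine.optimize_branch_lengths(tol=bl_tol)
    engine.tree.log_likelihood = logl
    return engine.tree


def search_ml_tree(
    alignment: Alignment,
    model: SubstModel,
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-4,
) -> Tree:
    """Best NNI-improved tree over randomized parsimony starting trees."""
    best_tree, best_logl = None, -np.inf
    for i in range(n_starts):
        start = parsimony_random_addition_tree(alignment, child_seed(seed, 0, i))
        t = nni_search(alignment, start, model, tol=tol)
        if t.log_likelihood > best_logl:
            best_tree, best_logl = t, t.log_likelihood
    return best_tree
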