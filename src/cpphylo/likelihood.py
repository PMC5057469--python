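"""Maximum-likelihood engine for GTR+Gamma on unrooted trees.

Felsenstein pruning over compressed site patterns, with per-pattern
rescaling against underflow.  The engine caches downward (subtree) and
upward (rest-of-tree) conditional likelihoods per node, which makes
single-branch likelihood curves cheap; branch lengths are optimized by
cycling Brent's method over branches, and model parameters by quasi-Newton
on a transformed unconstrained parameterization.

Gaps and IUPAC ambiguity codes are partial missing data: a tip's
conditional likelihood is 1 for every state compatible with the observed
character, so fully-gapped columns carry no signal.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .alignment import Alignment
from .model import SubstModel, discrete_gamma_rates, empirical_base_freqs
from .tree import Tree

MIN_BL = 1e-8
MAX_BL = 50.0
_TINY = 1e-300


def compress_patterns(masks: np.ndarray):
    """Unique columns of a (taxa, sites) bitmask matrix with multiplicities.

    Returns (patterns, weights): patterns is (taxa, n_patterns), weights the
    number of original columns matching each pattern.
    """
    cols, counts = np.unique(masks.T, axis=0, return_counts=True)
    return cols.T.copy(), counts.astype(float)


class TreeLikelihood:
    """Likelihood computations for one (alignment, tree, model) triple.

    The tree is copied on construction; the optimized copy is available as
    ``.tree``.  Topology edits (used by the NNI search) go through
    :meth:`refresh_topology`.
    """

    def __init__(self, alignment: Alignment, tree: Tree, model: SubstModel):
        leaf_labels = {n.label for n in tree.leaves()}
        missing = leaf_labels - set(alignment.taxa)
        if missing:
            raise ValueError(f"tree taxa absent from alignment: {sorted(missing)}")
        if len(leaf_labels) < 2:
            raise ValueError("need at least 2 taxa")
        self.alignment = alignment
        self.tree = tree.copy()
        rows = [alignment.taxa.index(n.label) for n in self.tree.leaves()]
        self._leaf_order = [n.label for n in self.tree.leaves()]
        masks = alignment.masks()[rows]
        self.patterns, self.weights = compress_patterns(masks)
        self._tips = {}
        for i, label in enumerate(self._leaf_order):
            bits = self.patterns[i]
            tip = np.empty((4, bits.size))
            for s in range(4):
                tip[s] = (bits >> s) & 1
            self._tips[label] = tip
        self.set_model(model)

    # ------------------------------------------------------------------
    def set_model(self, model: SubstModel) -> None:
        self.model = model
        self.rates = discrete_gamma_rates(model.alpha, model.n_categories)
        self._w, self._U, self._Uinv = model.eigensystem()
        self.refresh_topology()

    def refresh_topology(self) -> None:
        """Re-index the tree and invalidate cached partials."""
        self.nodes = self.tree.postorder()
        self._idx = {id(n): i for i, n in enumerate(self.nodes)}
        self._down = None
        self._up = None

    def _pmats(self, t: float) -> np.ndarray:
        """Transition matrices for all rate categories, shape (ncat, 4, 4)."""
        e = np.exp((self.rates[:, None] * self._w[None, :]) * t)  # (ncat, 4)
        P = np.matmul(self._U[None, :, :] * e[:, None, :], self._Uinv)
        return np.maximum(P, 0.0)

    # -- partials ------------------------------------------------------
    def _tip_cond(self, node) -> np.ndarray:
        return self._tips[node.label]

    def _compute_down(self) -> None:
        ncat = len(self.rates)
        P = self.weights.size
        down = [None] * len(self.nodes)
        scale = [None] * len(self.nodes)
        for i, node in enumerate(self.nodes):
            if node.is_leaf:
                down[i] = np.broadcast_to(self._tip_cond(node), (ncat, 4, P))
                scale[i] = 0.0
                continue
            acc = np.ones((ncat, 4, P))
            sc = 0.0
            for child in node.children:
                ci = self._idx[id(child)]
                acc = acc * np.matmul(self._pmats(child.length), down[ci])
                sc = sc + scale[ci]
            m = acc.max(axis=(0, 1))
            m = np.where(m > 0, m, 1.0)
            down[i] = acc / m
            scale[i] = sc + np.log(m)
        self._down = down
        self._dscale = scale

    def _compute_up(self) -> None:
        """up[n]: likelihood of everything outside n's subtree, as a function
        of the state at n, with the stationary frequencies folded in."""
        if self._down is None:
            self._compute_down()
        ncat = len(self.rates)
        P = self.weights.size
        pi = self.model.base_freqs
        up = [None] * len(self.nodes)
        uscale = [None] * len(self.nodes)
        ri = self._idx[id(self.tree.root)]
        up[ri] = np.broadcast_to(pi[None, :, None], (ncat, 4, P))
        uscale[ri] = 0.0
        for node in self.tree.preorder():
            if node.is_leaf:
                continue
            i = self._idx[id(node)]
            kids = node.children
            X = []
            for child in kids:
                ci = self._idx[id(child)]
                X.append(np.matmul(self._pmats(child.length), self._down[ci]))
            # prefix/suffix products for leave-one-out
            k = len(kids)
            pre = [None] * (k + 1)
            suf = [None] * (k + 1)
            pre[0] = np.ones((ncat, 4, P))
            for j in range(k):
                pre[j + 1] = pre[j] * X[j]
            suf[k] = np.ones((ncat, 4, P))
            for j in range(k - 1, -1, -1):
                suf[j] = suf[j + 1] * X[j]
            sib_scale_total = sum(self._dscale[self._idx[id(c)]] for c in kids)
            for j, child in enumerate(kids):
                ci = self._idx[id(child)]
                A = up[i] * pre[j] * suf[j + 1]
                out = np.matmul(self._pmats(child.length).transpose(0, 2, 1), A)
                m = out.max(axis=(0, 1))
                m = np.where(m > 0, m, 1.0)
                up[ci] = out / m
                uscale[ci] = (
                    uscale[i]
                    + sib_scale_total
                    - self._dscale[ci]
                    + np.log(m)
                )
        self._up = up
        self._uscale = uscale

    # -- likelihood ----------------------------------------------------
    def log_likelihood(self) -> float:
        self._compute_down()
        ri = self._idx[id(self.tree.root)]
        pi = self.model.base_freqs
        site = np.einsum("j,cjp->p", pi, self._down[ri]) / len(self.rates)
        return float(np.dot(self.weights, np.log(np.maximum(site, _TINY)) + self._dscale[ri]))

    def edge_context(self, node):
        """(out, out_scale, inner, inner_scale) for the branch above ``node``.

        ``out`` is the conditional likelihood of everything on the parent
        side (frequencies folded in); ``inner`` that of ``node``'s subtree.
        Requires cached partials (:meth:`prepare`).
        """
        parent = node.parent
        i = self._idx[id(node)]
        pi_idx = self._idx[id(parent)]
        out = self._up[pi_idx]
        sc = self._uscale[pi_idx]
        for sib in parent.children:
            if sib is node:
                continue
            si = self._idx[id(sib)]
            out = out * np.matmul(self._pmats(sib.length), self._down[si])
            sc = sc + self._dscale[si]
        m = out.max(axis=(0, 1))
        m = np.where(m > 0, m, 1.0)
        return out / m, sc + np.log(m), self._down[i], self._dscale[i]

    def edge_loglik(self, out, out_scale, inner, inner_scale, t: float) -> float:
        pm = self._pmats(t)
        site = (np.matmul(pm.transpose(0, 2, 1), out) * inner).sum(axis=1).mean(axis=0)
        return float(
            np.dot(self.weights, np.log(np.maximum(site, _TINY)) + out_scale + inner_scale)
        )

    def prepare(self) -> None:
        self._compute_down()
        self._compute_up()

    def edge_curve(self, out, out_scale, inner, inner_scale):
        """Fast single-branch log-likelihood function t -> logL.

        Precomputes the per-pattern outer product of the two flanking
        partials so each evaluation is one small matrix-vector product.
        """
        ncat = len(self.rates)
        G = (out[:, :, None, :] * inner[:, None, :, :]).reshape(ncat * 16, -1)
        const = out_scale + inner_scale

        def loglik(t: float) -> float:
            pm = self._pmats(t).reshape(ncat * 16)
            site = (pm @ G) / ncat
            return float(np.dot(self.weights, np.log(np.maximum(site, _TINY)) + const))

        return loglik

    # -- branch-length optimization -------------------------------------
    def optimize_branch_length(self, node, min_bl=MIN_BL, max_bl=MAX_BL) -> float:
        curve = self.edge_curve(*self.edge_context(node))
        res = minimize_scalar(
            lambda t: -curve(t),
            bounds=(min_bl, max_bl),
            method="bounded",
            options={"xatol": 1e-7},
        )
        best_t, best_l = float(res.x), -res.fun
        at_min = curve(min_bl)  # bounded Brent stalls short of the boundary
        if at_min >= best_l:
            best_t, best_l = min_bl, at_min
        current = curve(node.length)
        if best_l > current:
            node.length = best_t
        return max(best_l, current)

    def optimize_branch_lengths(
        self, tol=1e-6, max_rounds=10, min_bl=MIN_BL, max_bl=MAX_BL
    ) -> float:
        """Cycle Brent over all branches until the total gain per round < tol.

        Partials are rebuilt at the start of each round; a round whose joint
        update somehow lowers the likelihood is reverted, so the accepted
        trajectory is non-decreasing.
        """
        logl = self.log_likelihood()
        self.tree.converged = False
        for _ in range(max_rounds):
            saved = [n.length for n in self.nodes]
            self.prepare()
            for node in self.nodes:
                if node.parent is None:
                    continue
                self.optimize_branch_length(node, min_bl, max_bl)
            new_logl = self.log_likelihood()
            if new_logl < logl:
                for n, length in zip(self.nodes, saved):
                    n.length = length
                self._down = None
                self.tree.converged = True
                return self.log_likelihood()
            gain = new_logl - logl
            logl = new_logl
            if gain < tol:
                self.tree.converged = True
                return logl
        warnings.warn("branch-length optimization hit the round limit")
        return logl

    # -- model-parameter optimization ------------------------------------
    def optimize_model(self, tol=1e-8, max_iter=200) -> SubstModel:
        """ML estimates of exchangeabilities, frequencies and alpha with the
        topology and branch lengths held fixed."""
        if self.weights.size < 2:
            warnings.warn("degenerate alignment (single site pattern); model unchanged")
            return self.model
        m0 = self.model
        ncat = m0.n_categories
        x0 = np.concatenate(
            [
                np.log(np.maximum(m0.exchangeabilities[:5], 1e-6)),
                np.log(np.maximum(m0.base_freqs[:3] / m0.base_freqs[3], 1e-8)),
                [np.log(m0.alpha)],
            ]
        )

        def unpack(x):
            ex = np.concatenate([np.exp(x[:5]), [1.0]])
            f = np.concatenate([np.exp(x[5:8]), [1.0]])
            return SubstModel(ex, f / f.sum(), float(np.exp(x[8])), ncat)

        def objective(x):
            try:
                self.set_model(unpack(x))
            except (ValueError, np.linalg.LinAlgError):
                return 1e12
            return -self.log_likelihood()

        base = -objective(x0)
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=[(-10, 10)] * 8 + [(np.log(0.02), np.log(100.0))],
            options={"maxiter": max_iter, "ftol": tol},
        )
        best = unpack(res.x) if -res.fun >= base else m0
        self.set_model(best)
        return best


# ----------------------------------------------------------------------
# Functional wrappers (the module surface used by the pipeline and CLI)


def log_likelihood(alignment: Alignment, tree: Tree, model: SubstModel) -> float:
    """Log-likelihood of the alignment on the tree under GTR+Gamma."""
    return TreeLikelihood(alignment, tree, model).log_likelihood()


def optimize_branch_lengths(
    alignment: Alignment,
    tree: Tree,
    model: SubstModel,
    tol: float = 1e-6,
    max_rounds: int = 10,
) -> Tree:
    """Tree with ML branch lengths (topology fixed); ``tree.converged`` is
    False if the round limit was hit first."""
    engine = TreeLikelihood(alignment, tree, model)
    engine.optimize_branch_lengths(tol=tol, max_rounds=max_rounds)
    return engine.tree


def optimize_model_parameters(
    alignment: Alignment, tree: Tree, model: SubstModel
) -> SubstModel:
    """ML model parameters on a fixed tree with fixed branch lengths."""
    return TreeLikelihood(alignment, tree, model).optimize_model()


def fit_model_and_branch_lengths(
    alignment: Alignment,
    tree: Tree,
    model: SubstModel | None = None,
    cycles: int = 2,
):
    """Alternate model and branch-length optimization on a fixed topology.

    Returns (tree, model, logL).  This is the "optimize a GTR+Gamma model on
    the ML tree" step of the rate pipeline.
    """
    if model is None:
        model = SubstModel(base_freqs=empirical_base_freqs(alignment))
    engine = TreeLikelihood(alignment, tree, model)
    logl = engine.optimize_branch_lengths()
    for _ in range(cycles):
        engine.optimize_model()
        logl = engine.optimize_branch_lengths()
    return engine.tree, engine.model, logl
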