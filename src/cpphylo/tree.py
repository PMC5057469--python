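"""Phylogenetic trees: arbitrarily rooted storage, unrooted semantics.

Trees are stored with an arbitrary root (preferably a trifurcation, the
conventional unrooted representation), but every likelihood, length and
bipartition computation is invariant to the rooting.  Branch lengths are
expected substitutions per site.
"""

from __future__ import annotations

import warnings

import dendropy


class Node:
    __slots__ = ("label", "children", "parent", "length")

    def __init__(self, label=None, length=0.0):
        self.label = label
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = float(length)

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """A tree over labelled leaves with non-negative branch lengths."""

    def __init__(self, root: Node):
        self.root = root
        self.converged: bool = True  # cleared by optimizers on non-convergence
        self._validate()

    def _validate(self) -> None:
        labels = [n.label for n in self.leaves()]
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        for node in self.postorder():
            if node.length < 0 or node.length != node.length:
                raise ValueError(f"negative or non-finite branch length at {node.label!r}")

    # -- traversal -----------------------------------------------------
    def postorder(self):
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out[::-1]

    def preorder(self):
        return self.postorder()[::-1]

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def taxa(self) -> list[str]:
        return sorted(n.label for n in self.leaves())

    def __len__(self) -> int:
        return len(self.leaves())

    # -- basic quantities ----------------------------------------------
    def tree_length(self) -> float:
        """Sum of all branch lengths (the root's stored length is not a branch)."""
        return sum(n.length for n in self.postorder() if n.parent is not None)

    def bipartitions(self) -> set[frozenset]:
        """Informative splits (both sides >= 2 taxa), each stored as its
        canonical side: the smaller taxon set, ties broken lexicographically."""
        all_taxa = frozenset(n.label for n in self.leaves())
        below: dict[Node, frozenset] = {}
        splits = set()
        for node in self.postorder():
            if node.is_leaf:
                below[node] = frozenset([node.label])
            else:
                below[node] = frozenset().union(*(below[c] for c in node.children))
            if node.parent is not None and 2 <= len(below[node]) <= len(all_taxa) - 2:
                splits.add(canonical_split(below[node], all_taxa))
        return splits

    # -- copy / reroot --------------------------------------------------
    def copy(self) -> "Tree":
        def clone(n: Node) -> Node:
            m = Node(n.label, n.length)
            for c in n.children:
                m.add(clone(c))
            return m

        t = Tree(clone(self.root))
        t.converged = self.converged
        return t

    def reroot(self, leaf_label: str) -> "Tree":
        """A copy re-rooted at the node adjacent to the named leaf."""
        t = self.copy()
        target = next(n for n in t.postorder() if n.label == leaf_label)
        new_root = target.parent
        if new_root is None:
            return t
        # reverse parent pointers along the path new_root -> old root;
        # the edge between path[i] and path[i+1] is stored on path[i]
        path = []
        n = new_root
        while n is not None:
            path.append(n)
            n = n.parent
        orig_len = [n.length for n in path]
        for i, (child, parent) in enumerate(zip(path[:-1], path[1:])):
            parent.children.remove(child)
            child.add(parent)
            parent.length = orig_len[i]
        new_root.parent = None
        new_root.length = 0.0
        out = Tree(new_root)
        out.converged = t.converged
        return out

    def unroot(self) -> "Tree":
        """Collapse a bifurcating root into the conventional trifurcation."""
        t = self.copy()
        r = t.root
        if len(r.children) == 2 and not all(c.is_leaf for c in r.children):
            a, b = r.children
            keep, fold = (a, b) if not a.is_leaf else (b, a)
            # promote keep's children to the root; the two root branches
            # merge into the single unrooted branch carried by fold
            r.children = list(keep.children) + [fold]
            for c in keep.children:
                c.parent = r
            fold.length = fold.length + keep.length
            fold.parent = r
        return Tree(t.root)

    def newick(self, precision: int = 10) -> str:
        """Canonical Newick string: children sorted by smallest descendant label."""

        def key(n: Node) -> str:
            while not n.is_leaf:
                n = min(n.children, key=key)
            return n.label

        def fmt(n: Node) -> str:
            if n.is_leaf:
                core = n.label
            else:
                inner = ",".join(fmt(c) for c in sorted(n.children, key=key))
                core = f"({inner})"
            if n.parent is None:
                return core
            return f"{core}:{n.length:.{precision}g}"

        return fmt(self.root) + ";"

    def __repr__(self) -> str:
        return f"Tree({len(self)} leaves)"


def prune_to(tree: Tree, keep_labels) -> Tree:
    """Restriction of the tree to a taxon subset.

    Unary nodes left by the removal are suppressed, their branch lengths
    summed onto the retained child, so path lengths between kept taxa are
    preserved.
    """
    keep = set(keep_labels)
    missing = keep - set(tree.taxa)
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa after pruning")

    def rec(n: Node) -> Node | None:
        if n.is_leaf:
            return Node(n.label, n.length) if n.label in keep else None
        kids = [k for k in (rec(c) for c in n.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].length += n.length
            return kids[0]
        m = Node(n.label, n.length)
        for k in kids:
            m.add(k)
        return m

    root = rec(tree.root)
    while root is not None and len(root.children) == 1:
        root = root.children[0]
        root.parent = None
    root.length = 0.0
    return Tree(root)


def canonical_split(side: frozenset, all_taxa: frozenset) -> frozenset:
    other = all_taxa - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return min(side, other, key=lambda s: tuple(sorted(s)))


def tree_length(tree: Tree) -> float:
    return tree.tree_length()


# ----------------------------------------------------------------------
# Newick IO (parsing via dendropy; writing via the canonical formatter)


def _from_dendropy(dtree: dendropy.Tree) -> Tree:
    missing = False

    def convert(dnode) -> Node:
        nonlocal missing
        label = dnode.taxon.label if dnode.taxon is not None else None
        length = dnode.edge.length
        if length is None:
            length = 0.0
            if dnode.parent_node is not None:
                missing = True
        n = Node(label, length)
        for c in dnode.child_nodes():
            n.add(convert(c))
        return n

    root = convert(dtree.seed_node)
    if missing:
        warnings.warn("missing branch lengths in Newick input; defaulting to 0")
    return Tree(root)


def parse_newick(text: str) -> Tree:
    dtree = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True, suppress_internal_node_taxa=True
    )
    return _from_dendropy(dtree)


def read_newick(path) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")
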