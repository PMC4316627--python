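"""Lightweight phylogenetic tree container.

A :class:`PhyloTree` is a node-linked tree whose edges carry lengths in
expected substitutions per site and (optionally) support values in [0, 100].
Rootedness follows the arity convention: a tree whose basal node has exactly
two children is rooted; a basal node of degree >= 3 marks an unrooted tree.

The container is deliberately small: parsing, screening algebra, neighbor
joining and likelihood all build on these few primitives.
"""

from __future__ import annotations

from typing import Callable, Iterable, Iterator


class TreeError(ValueError):
    """Structural problem with a tree."""


class Node:
    """A tree node; ``length`` and ``support`` describe the edge above it."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 support: float | None = None):
        self.name = name
        self.length = float(length)
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = self.name if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {kind} len={self.length:g}>"


class PhyloTree:
    """Rooted or unrooted tree with branch lengths and optional supports."""

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self.validate()

    # -- structural queries -------------------------------------------------

    @property
    def rooted(self) -> bool:
        return len(self.root.children) == 2

    def nodes(self) -> Iterator[Node]:
        return self.root.preorder()

    def leaves(self) -> list[Node]:
        return [n for n in self.root.preorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def edges(self) -> Iterator[Node]:
        """Yield every non-root node; each stands for the edge above it."""
        for n in self.root.preorder():
            if n is not self.root:
                yield n

    def total_length(self) -> float:
        return sum(n.length for n in self.edges())

    def find_leaf(self, name: str) -> Node:
        for n in self.leaves():
            if n.name == name:
                return n
        raise TreeError(f"leaf {name!r} not in tree")

    def validate(self) -> None:
        names = [n.name for n in self.leaves()]
        if len(names) != len(set(names)):
            dup = sorted({x for x in names if names.count(x) > 1})
            raise TreeError(f"duplicate leaf labels: {dup}")
        if any(x is None or x == "" for x in names):
            raise TreeError("every leaf must be labeled")
        for n in self.edges():
            if n.length < 0:
                raise TreeError(f"negative branch length {n.length} above "
                                f"{n.name or 'internal node'}")

    # -- construction helpers ----------------------------------------------

    def copy(self) -> "PhyloTree":
        def rec(n: Node) -> Node:
            m = Node(n.name, n.length, n.support)
            for c in n.children:
                m.add(rec(c))
            return m
        return PhyloTree(rec(self.root), validate=False)

    def leafset_below(self, node: Node) -> frozenset[str]:
        return frozenset(n.name for n in node.preorder() if n.is_leaf)

    # -- topology surgery ---------------------------------------------------

    def restrict(self, keep: Iterable[str]) -> "PhyloTree":
        """Tree induced by the leaf subset, unary nodes suppressed.

        Lengths along suppressed paths are summed; the support kept on a
        merged edge is that of its deepest constituent edge.
        """
        keep = set(keep)
        missing = keep - set(self.leaf_names)
        if missing:
            raise TreeError(f"unknown leaves: {sorted(missing)}")
        if not keep:
            raise TreeError("cannot restrict to an empty leaf set")

        def rec(n: Node) -> Node | None:
            if n.is_leaf:
                if n.name in keep:
                    return Node(n.name, n.length, n.support)
                return None
            kids = [k for k in (rec(c) for c in n.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                k = kids[0]
                k.length += n.length
                return k
            m = Node(n.name, n.length, n.support)
            for k in kids:
                m.add(k)
            return m

        root = rec(self.root)
        # descend through any remaining unary chain at the top
        while root is not None and len(root.children) == 1:
            root = root.children[0]
            root.parent = None
            root.length = 0.0
            root.support = None
        if root is None:
            raise TreeError("restriction removed every leaf")
        root.parent = None
        root.length = 0.0
        return PhyloTree(root, validate=False)

    def unroot(self) -> "PhyloTree":
        """Collapse a 2-child basal node; no-op on already-unrooted trees."""
        t = self.copy()
        r = t.root
        if len(r.children) != 2:
            return t
        a, b = r.children
        # absorb one side into the other; keep an internal node as base
        keepme, other = (a, b) if not a.is_leaf else (b, a)
        if keepme.is_leaf:
            raise TreeError("cannot unroot a two-leaf tree")
        merged = keepme
        merged.parent = None
        other.length += keepme.length
        if other.support is None:
            other.support = keepme.support
        merged.length = 0.0
        merged.support = None
        merged.add(other)
        return PhyloTree(merged, validate=False)

    def reroot_on_edge(self, child_name_or_node, dist_from_child: float | None = None
                       ) -> "PhyloTree":
        """Root the tree on the edge above the given node.

        ``dist_from_child`` positions the new root along the edge (default:
        midpoint). Returns a new rooted tree; the original is untouched.
        """
        t = self.copy()
        if isinstance(child_name_or_node, Node):
            # locate the corresponding node in the copy by path
            path = []
            n = child_name_or_node
            while n.parent is not None:
                path.append(n.parent.children.index(n))
                n = n.parent
            node = t.root
            for i in reversed(path):
                node = node.children[i]
        else:
            target = str(child_name_or_node)
            node = None
            for n in t.nodes():
                if n.name == target:
                    node = n
                    break
            if node is None:
                raise TreeError(f"no node named {target!r}")
        if node.parent is None:
            raise TreeError("cannot reroot on the edge above the root")
        edge_len = node.length
        if dist_from_child is None:
            dist_from_child = edge_len / 2.0
        if not 0.0 <= dist_from_child <= edge_len + 1e-12:
            raise TreeError("root position outside the edge")

        support = node.support

        def flipped(n: Node, coming_from: Node) -> Node:
            """Re-hang ``n`` with ``coming_from`` excluded; the old parent
            becomes a child carrying n's old upward edge."""
            m = Node(n.name, 0.0, None)
            for c in n.children:
                if c is coming_from:
                    continue
                m.add(_copy_sub(c))
            if n.parent is not None:
                p = flipped(n.parent, n)
                p.length = n.length
                p.support = n.support
                m.add(p)
            return m

        def _copy_sub(n: Node) -> Node:
            m = Node(n.name, n.length, n.support)
            for c in n.children:
                m.add(_copy_sub(c))
            return m

        new_root = Node(None, 0.0, None)
        down = _copy_sub(node)
        down.length = dist_from_child
        up = flipped(node.parent, node)
        up.length = edge_len - dist_from_child
        up.support = support
        down.support = support
        new_root.add(down)
        new_root.add(up)
        out = PhyloTree(new_root, validate=False)
        # suppress any unary node created where the old basal node sat
        for n in list(out.nodes()):
            if len(n.children) == 1 and n.parent is not None and not n.is_leaf:
                c = n.children[0]
                c.length += n.length
                if c.support is None:
                    c.support = n.support
                c.parent = n.parent
                n.parent.children[n.parent.children.index(n)] = c
        return out

    # -- path metrics -------------------------------------------------------

    def path_length(self, a: str, b: str) -> float:
        anc: dict[int, float] = {}
        n = self.find_leaf(a)
        d = 0.0
        while n is not None:
            anc[id(n)] = d
            d += n.length
            n = n.parent
        n = self.find_leaf(b)
        d = 0.0
        while n is not None:
            if id(n) in anc:
                return d + anc[id(n)]
            d += n.length
            n = n.parent
        raise TreeError("leaves are not connected")  # pragma: no cover

    def scale_subtree(self, node: Node, factor: float) -> None:
        """Multiply every edge strictly inside the subtree by ``factor``."""
        for n in node.preorder():
            if n is not node:
                n.length *= factor

    def __str__(self) -> str:
        from .formats import write_newick
        return write_newick(self)


def random_topology(names: list[str], rng, rooted: bool = False,
                    length_sampler: Callable[[], float] | None = None) -> PhyloTree:
    """Random binary topology over the given leaf names (sequential joins).

    Used by the simulator and by property tests that need arbitrary trees.
    """
    if len(names) < 2:
        raise TreeError("need at least two leaves")
    draw = length_sampler or (lambda: float(rng.uniform(0.05, 0.5)))
    nodes = [Node(nm, draw()) for nm in names]
    # random sequence of joins
    while len(nodes) > (2 if rooted else 3):
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        m = Node(None, draw())
        m.add(a)
        m.add(b)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [m]
    root = Node(None, 0.0)
    for n in nodes:
        root.add(n)
    if len(names) == 2 and not rooted:
        # a two-leaf tree is degenerate; represent as rooted cherry
        pass
    return PhyloTree(root, validate=False)
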