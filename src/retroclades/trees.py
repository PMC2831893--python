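"""Phylogenetic trees with per-branch partition labels.

Trees are rooted node structures carrying branch lengths (expected
substitutions per codon on the branch above each node) and an integer
*partition label* per branch.  Partition 0 is the background; partition 1
(and higher) marks foreground clades such as a recently inserted retrogene
clade whose dN/dS is modelled separately.

The Newick dialect uses ``#<int>`` after a node (before or after the branch
length) to label the branch, e.g.::

    ((mouse:0.1,(retro1:0.05,retro2:0.05):0.02 #1):0.15,rat:0.2);

By default a label on an internal branch propagates to the whole subtree
below it (a labelled clade); pass ``propagate_labels=False`` to label the
stem branch only.

This parser is written in-package because the ``#<int>`` branch-label
dialect is not part of standard Newick and general-purpose readers either
reject it or fold it into taxon names.
"""

from __future__ import annotations

import re
from typing import Callable, Iterator


class Node:
    """A tree node; ``length`` and ``partition`` describe the branch above."""

    __slots__ = ("name", "length", "partition", "children", "parent", "_label_explicit")

    def __init__(
        self,
        name: str | None = None,
        length: float | None = None,
        partition: int = 0,
    ) -> None:
        self.name = name
        self.length = length
        self.partition = partition
        self.children: list[Node] = []
        self.parent: Node | None = None
        self._label_explicit = False

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.name or ''} {kind} t={self.length} p={self.partition}>"


class Tree:
    """A rooted phylogeny with branch lengths and branch partition labels."""

    def __init__(self, root: Node) -> None:
        self.root = root
        self._validate()

    # ------------------------------------------------------------------ basics
    def postorder(self) -> Iterator[Node]:
        def walk(node: Node) -> Iterator[Node]:
            for child in node.children:
                yield from walk(child)
            yield node

        return walk(self.root)

    def preorder(self) -> Iterator[Node]:
        def walk(node: Node) -> Iterator[Node]:
            yield node
            for child in node.children:
                yield from walk(child)

        return walk(self.root)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def branches(self) -> list[Node]:
        """All non-root nodes (each identifies the branch above it)."""
        return [n for n in self.postorder() if n is not self.root]

    def n_partitions(self) -> int:
        return max(n.partition for n in self.branches()) + 1 if self.branches() else 1

    def find(self, name: str) -> Node:
        for node in self.postorder():
            if node.name == name:
                return node
        raise KeyError(f"no node named {name!r}")

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.branches())

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length, node.partition)
            new._label_explicit = node._label_explicit
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root))

    def _validate(self) -> None:
        names = self.leaf_names()
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf names: {dupes}")
        for node in self.branches():
            if node.length is not None and not (node.length >= 0.0):
                raise ValueError(
                    f"negative or non-finite branch length {node.length} "
                    f"above {node.name or 'internal node'}"
                )
        labels = sorted({n.partition for n in self.branches()}) or [0]
        if labels != list(range(len(labels))) or labels[0] != 0:
            raise ValueError(
                f"partition labels must be contiguous starting at 0, got {labels}"
            )

    # ------------------------------------------------------------------ rerooting
    def reroot_on_branch(self, child_name: str, fraction: float = 0.5) -> "Tree":
        """Return a copy rerooted on the branch above the named node.

        The branch is split ``fraction`` of the way from the child towards
        its parent; the partition label of the split branch is kept on both
        halves.  For a time-reversible substitution model the likelihood is
        invariant under this operation (the pulley principle).
        """
        if not (0.0 <= fraction <= 1.0):
            raise ValueError("fraction must lie in [0, 1]")
        tree = self.copy()
        child = tree.find(child_name)
        if child is tree.root:
            raise ValueError("cannot reroot on the branch above the root")
        if child.length is None:
            raise ValueError("branch has no length to split")
        total = child.length
        path: list[Node] = []  # child's parent up to (and including) the old root
        node = child.parent
        while node is not None:
            path.append(node)
            node = node.parent
        # Branch lengths/partitions above each path node, before reversal.
        old_branch = [(n.length, n.partition) for n in path]
        # Detach the path edges.
        path[0].children.remove(child)
        for upper, lower in zip(path[1:], path[:-1]):
            upper.children.remove(lower)
        for n in path:
            n.parent = None
        new_root = Node(None, None, 0)
        new_root.add_child(child)
        child.length = total * fraction
        new_root.add_child(path[0])
        path[0].length = total * (1.0 - fraction)
        path[0].partition = child.partition
        # Reverse the remaining edges: the branch that sat above path[i]
        # now sits above path[i+1].
        for i in range(len(path) - 1):
            path[i].add_child(path[i + 1])
            path[i + 1].length, path[i + 1].partition = old_branch[i]
        _splice_unary(new_root)
        return Tree(new_root)

    def collapse_root(self) -> "Tree":
        """Return a copy where a bifurcating root is collapsed onto one child.

        The two root-adjacent branch lengths are summed onto a single branch,
        removing the non-identifiable root placement of a reversible model.
        Only performed when both root branches carry the same partition label
        and the first root child is internal; otherwise a copy is returned
        unchanged.
        """
        tree = self.copy()
        root = tree.root
        if len(root.children) != 2:
            return tree
        a, b = root.children
        if a.partition != b.partition:
            return tree
        host, other = (a, b) if not a.is_leaf else (b, a)
        if host.is_leaf:
            return tree
        other.length = (other.length or 0.0) + (host.length or 0.0)
        root.children.remove(other)
        root.children.remove(host)
        host.parent = None
        other.parent = None
        host.length = None
        host.add_child(other)
        return Tree(host)

    # ------------------------------------------------------------------ newick
    def to_newick(self, *, labels: bool = True, precision: int = 12) -> str:
        return _to_newick(self.root, labels=labels, precision=precision) + ";"


def _splice_unary(node: Node) -> None:
    """Remove internal nodes with exactly one child below ``node``, merging
    branch lengths.  A degree-2 node joining branches of *different*
    partitions is kept: merging would reassign part of one partition's
    length to the other and change the model."""
    for child in list(node.children):
        _splice_unary(child)
    if (
        len(node.children) == 1
        and node.parent is not None
        and node.children[0].partition == node.partition
    ):
        (child,) = node.children
        child.length = (child.length or 0.0) + (node.length or 0.0)
        parent = node.parent
        idx = parent.children.index(node)
        parent.children[idx] = child
        child.parent = parent


def _to_newick(node: Node, *, labels: bool, precision: int) -> str:
    if node.is_leaf:
        out = node.name or ""
    else:
        inner = ",".join(_to_newick(c, labels=labels, precision=precision) for c in node.children)
        out = f"({inner})" + (node.name or "")
    if node.length is not None:
        out += f":{node.length:.{precision}g}"
    if labels and node.parent is not None and node.partition != _effective_parent_label(node):
        out += f" #{node.partition}"
    return out


def _effective_parent_label(node: Node) -> int:
    parent = node.parent
    if parent is None or parent.parent is None:
        return 0
    return parent.partition


_TOKEN = re.compile(
    r"\s*(?:"
    r"(?P<punct>[(),;])"
    r"|:(?P<length>[-+0-9.eE]+)"
    r"|#(?P<label>\d+)"
    r"|(?P<name>(?:'[^']*')|[^\s(),;:#]+)"
    r")"
)


def parse_newick(text: str, *, propagate_labels: bool = True) -> Tree:
    """Parse Newick with the ``#<int>`` branch-partition dialect.

    ``propagate_labels=True`` (default) interprets a label on an internal
    branch as labelling the whole clade below it, matching a clade-model
    foreground; deeper explicit labels override.  With ``False`` only
    explicitly labelled branches leave the background partition.
    """
    tokens = list(_TOKEN.finditer(text))
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def advance():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_clade() -> Node:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise ValueError("unexpected end of Newick string")
        if tok.group("punct") == "(":
            advance()
            node = Node()
            node.add_child(parse_clade())
            while peek() is not None and peek().group("punct") == ",":
                advance()
                node.add_child(parse_clade())
            if peek() is None or peek().group("punct") != ")":
                raise ValueError("unbalanced parentheses in Newick string")
            advance()
        else:
            node = Node()
        # suffix: optional name, then length / label in either order
        while peek() is not None and peek().group("punct") is None:
            tok = advance()
            if tok.group("name") is not None:
                if node.name is not None:
                    raise ValueError(f"unexpected token {tok.group('name')!r}")
                node.name = tok.group("name").strip("'")
            elif tok.group("length") is not None:
                node.length = float(tok.group("length"))
            elif tok.group("label") is not None:
                node.partition = int(tok.group("label"))
                node._label_explicit = True
        return node

    root = parse_clade()
    if peek() is None or peek().group("punct") != ";":
        raise ValueError("Newick string must end with ';'")
    advance()
    if peek() is not None:
        raise ValueError("trailing characters after ';'")
    if root.is_leaf and root.name is None:
        raise ValueError("empty Newick string")

    if propagate_labels:
        for child in root.children:
            _propagate(child, 0)
    return Tree(root)


def _propagate(node: Node, inherited: int) -> None:
    if not node._label_explicit:
        node.partition = inherited
    for child in node.children:
        _propagate(child, node.partition)


def load_tree(source, *, propagate_labels: bool = True) -> Tree:
    """Load a tree from a Newick string or a path to a Newick file."""
    import os

    text = str(source)
    if os.path.exists(text):
        with open(text) as fh:
            text = fh.read()
    return parse_newick(text.strip(), propagate_labels=propagate_labels)
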