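"""Rooted species trees.

A thin rooted-tree container used by the simulator and the parsimony engine.
Newick parsing is delegated to :mod:`dendropy`; writing is done here because
the reconstruction output needs custom ``[+g, -l]`` branch comments that no
standard writer emits.

Every node carries a name (internal nodes are auto-named ``N1``, ``N2``, ... in
preorder when the input leaves them anonymous) and a branch length (default
1.0).  A *branch* is identified by the name of its child node; the root has no
branch.
"""

from __future__ import annotations

from typing import Callable, Iterator, Optional

import dendropy


class TreeError(ValueError):
    """Malformed or unusable tree input."""


class TreeNode:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str = "", length: float = 1.0,
                 children: Optional[list["TreeNode"]] = None):
        self.name = name
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        for child in children or []:
            self.add_child(child)

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, n_children={len(self.children)})"


class SpeciesTree:
    """Rooted tree over named species.

    Invariants enforced at construction: exactly one root, unique nonempty tip
    names, every internal node with >= 2 children.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._autoname()
        self._validate()
        self._by_name = {n.name: n for n in self.preorder()}

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        return cls._from_dendropy(dtree)

    @classmethod
    def read(cls, path) -> "SpeciesTree":
        dtree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls._from_dendropy(dtree)

    @classmethod
    def _from_dendropy(cls, dtree: dendropy.Tree) -> "SpeciesTree":
        seed = dtree.seed_node
        if len(seed.child_nodes()) >= 3:
            raise TreeError(
                "input tree is unrooted (basal polytomy of "
                f"{len(seed.child_nodes())}); a rooted tree is required"
            )

        def convert(dnode) -> TreeNode:
            if dnode.is_leaf():
                name = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            else:
                name = dnode.label or ""
            length = dnode.edge.length if dnode.edge.length is not None else 1.0
            node = TreeNode(name=name, length=float(length))
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(seed))

    def to_newick(self, branch_comment: Optional[Callable[[TreeNode], str]] = None,
                  include_lengths: bool = True) -> str:
        """Serialize; ``branch_comment(node)`` may return a ``[...]`` tag body."""

        def render(node: TreeNode) -> str:
            if node.children:
                inner = ",".join(render(c) for c in node.children)
                text = f"({inner}){node.name}"
            else:
                text = node.name
            if node.parent is not None and include_lengths:
                text += f":{node.length:g}"
            if branch_comment is not None and node.parent is not None:
                comment = branch_comment(node)
                if comment:
                    text += f"[{comment}]"
            return text

        return render(self.root) + ";"

    # ------------------------------------------------------------ traversal
    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_names(self) -> list[str]:
        return [t.name for t in self.tips()]

    def branches(self) -> list[TreeNode]:
        """All non-root nodes; each defines the branch from its parent."""
        return [n for n in self.preorder() if n.parent is not None]

    def node(self, name: str) -> TreeNode:
        return self._by_name[name]

    def clade_tips(self, node: TreeNode) -> frozenset[str]:
        return frozenset(
            t.name for t in self._subtree_tips(node)
        )

    def _subtree_tips(self, node: TreeNode) -> list[TreeNode]:
        if node.is_tip:
            return [node]
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_tip:
                out.append(n)
            else:
                stack.extend(n.children)
        return out

    def is_ancestor(self, a: TreeNode, b: TreeNode) -> bool:
        """True if ``a`` lies on the path from the root to ``b`` (a != b)."""
        node = b.parent
        while node is not None:
            if node is a:
                return True
            node = node.parent
        return False

    # ------------------------------------------------------------ checks
    def _autoname(self) -> None:
        counter = 0
        for node in self.preorder():
            if not node.name:
                counter += 1
                node.name = f"N{counter}"

    def _validate(self) -> None:
        tips = self.tip_names()
        if not tips:
            raise TreeError("tree has no tips")
        if len(set(tips)) != len(tips):
            raise TreeError("tip names are not unique")
        names = [n.name for n in self.preorder()]
        if len(set(names)) != len(names):
            raise TreeError("node names are not unique after auto-naming")
        for node in self.preorder():
            if node.children and len(node.children) < 2 and node is not self.root:
                raise TreeError(f"internal node {node.name!r} has a single child")
            if node is self.root and len(node.children) == 1:
                raise TreeError("root has a single child")
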