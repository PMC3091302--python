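"""Rooted species trees with named internal nodes.

A thin, explicit tree structure tailored to direction-dependent
reconstruction: exactly one root, parent/child links, polytomies allowed.
Newick parsing and serialization are delegated to dendropy; unnamed
internal nodes are auto-named ``N1..Nk`` in preorder so that event
ledgers are stable and comparable across runs.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import dendropy

__all__ = ["TreeNode", "RootedTree"]


class TreeNode:
    """One node of a rooted tree."""

    __slots__ = ("name", "parent", "children")

    def __init__(self, name: str, parent: "TreeNode | None" = None):
        self.name = name
        self.parent = parent
        self.children: list[TreeNode] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, leaf={self.is_leaf})"


class RootedTree:
    """Rooted phylogeny with unique node names and polytomy support.

    Parameters
    ----------
    root:
        Root node of an already linked ``TreeNode`` structure.

    Notes
    -----
    Node names must be unique. Internal nodes without a name are
    assigned ``N<k>`` in preorder (root first), a deterministic scheme
    so repeated runs label ancestors identically.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._autoname()
        self._index: dict[str, TreeNode] = {}
        for node in self.preorder():
            if node.name in self._index:
                raise ValueError(f"duplicate node name {node.name!r}")
            self._index[node.name] = node

    # -- construction ----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "RootedTree":
        """Parse a Newick string into a rooted tree (branch lengths ignored)."""
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=False
            )
        except dendropy.utility.error.DataParseError as exc:
            raise ValueError(f"malformed or duplicate-labelled Newick: {exc}") from exc
        return cls._from_dendropy(dtree)

    @classmethod
    def _from_dendropy(cls, dtree: dendropy.Tree) -> "RootedTree":
        def convert(dnode, parent):
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = TreeNode(label or "", parent)
            for child in dnode.child_nodes():
                node.children.append(convert(child, node))
            return node

        return cls(convert(dtree.seed_node, None))

    def _autoname(self) -> None:
        counter = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.name:
                if node.is_leaf:
                    raise ValueError("leaf without a label")
                counter += 1
                node.name = f"N{counter}"
            stack.extend(reversed(node.children))

    # -- traversal -------------------------------------------------------

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def node(self, name: str) -> TreeNode:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"no node named {name!r} in tree") from None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __len__(self) -> int:
        return len(self._index)

    # -- queries ---------------------------------------------------------

    def ancestors(self, name: str) -> list[TreeNode]:
        """Nodes on the path from ``name``'s parent up to the root."""
        out = []
        node = self.node(name).parent
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    def mrca(self, names: Iterable[str]) -> TreeNode:
        """Most recent common ancestor of the named nodes."""
        names = list(names)
        if not names:
            raise ValueError("mrca of an empty set is undefined")
        paths = []
        for name in names:
            node = self.node(name)
            path = [node]
            while node.parent is not None:
                node = node.parent
                path.append(node)
            paths.append(list(reversed(path)))
        mrca = None
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                mrca = level[0]
            else:
                break
        assert mrca is not None  # all paths share the root
        return mrca

    def subtree_leaves(self, name: str) -> list[str]:
        start = self.node(name)
        out = []
        stack = [start]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node.name)
            stack.extend(reversed(node.children))
        return out

    def is_ancestor_or_self(self, anc: str, desc: str) -> bool:
        node = self.node(desc)
        target = self.node(anc)
        while node is not None:
            if node is target:
                return True
            node = node.parent
        return False

    # -- serialization ---------------------------------------------------

    def to_newick(self, include_internal_names: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return _quote(node.name)
            inner = ",".join(fmt(c) for c in node.children)
            label = _quote(node.name) if include_internal_names else ""
            return f"({inner}){label}"

        return fmt(self.root) + ";"

    def to_dendropy(
        self, taxon_namespace: dendropy.TaxonNamespace | None = None
    ) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=tns)

        def build(node: TreeNode, dnode) -> None:
            if node.is_leaf:
                dnode.taxon = tns.require_taxon(label=node.name)
            else:
                dnode.label = node.name
                for child in node.children:
                    build(child, dnode.new_child())

        build(self.root, dtree.seed_node)
        dtree.is_rooted = True
        return dtree

    def root_on(self, outgroup: str) -> "RootedTree":
        """Re-root so that the named leaf is the outgroup.

        Gain/loss inference is direction-dependent, so trees whose rooting
        is not trusted should be explicitly rooted on an outgroup taxon.
        Internal node names are regenerated (preorder ``N<k>``).
        """
        if outgroup not in self._index or not self.node(outgroup).is_leaf:
            raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
        dtree = self.to_dendropy()
        target = None
        for leaf in dtree.leaf_node_iter():
            if leaf.taxon.label == outgroup:
                target = leaf
                break
        dtree.reroot_at_edge(target.edge, update_bipartitions=False)
        rerooted = RootedTree._from_dendropy(dtree)
        for node in rerooted.preorder():
            if not node.is_leaf:
                node.name = ""
        return RootedTree(rerooted.root)

    def copy(self) -> "RootedTree":
        def clone(node: TreeNode, parent: TreeNode | None) -> TreeNode:
            new = TreeNode(node.name, parent)
            new.children = [clone(c, new) for c in node.children]
            return new

        return RootedTree(clone(self.root, None))

    def __repr__(self) -> str:  # pragma: no cover
        return f"RootedTree({len(self.leaves())} leaves, {len(self)} nodes)"


def _quote(name: str) -> str:
    if any(ch in name for ch in "(),:;' \t"):
        return "'" + name.replace("'", "''") + "'"
    return name
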