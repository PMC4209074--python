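"""Rooted-tree helpers on top of dendropy.

All reconciliation code works on rooted :class:`dendropy.Tree` objects.
:class:`TreeIndex` precomputes parent pointers, depths and stable labels
so that LCA queries and ancestor walks are cheap dictionary lookups.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Union

import dendropy

Nested = Union[str, tuple]


def tree_from_nested(spec: Nested, branch_length: float = 1.0) -> dendropy.Tree:
    """Build a rooted tree from a nested-tuple description.

    A leaf is a label string; an internal node is either a tuple of
    children ``(child, child, ...)`` or a labelled tuple whose first
    element is the label string prefixed with ``=`` — e.g.
    ``("=T", "Sm", (...))`` names the node ``T``.  Every edge gets
    ``branch_length``.
    """
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(node_spec: Nested) -> dendropy.Node:
        node = dendropy.Node()
        node.edge.length = branch_length
        if isinstance(node_spec, str):
            node.taxon = taxa.require_taxon(label=node_spec)
            return node
        children = list(node_spec)
        if children and isinstance(children[0], str) and children[0].startswith("="):
            node.label = children[0][1:]
            children = children[1:]
        for child_spec in children:
            node.add_child(build(child_spec))
        return node

    tree.seed_node = build(spec)
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


def parse_newick(source: str, *, is_path: bool = False) -> dendropy.Tree:
    """Parse one rooted Newick tree from a string or file path.

    Branch lengths and support values are tolerated and preserved but
    reconciliation ignores them.
    """
    kwargs = dict(schema="newick", preserve_underscores=True,
                  suppress_internal_node_taxa=False)
    if is_path:
        tree = dendropy.Tree.get(path=source, **kwargs)
    else:
        tree = dendropy.Tree.get(data=source, **kwargs)
    tree.is_rooted = True
    return tree


def node_name(node: dendropy.Node) -> Optional[str]:
    """Label of a node: taxon label for leaves, node label otherwise."""
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or None


class TreeIndex:
    """Constant-time parent/depth/label access and LCA queries."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.nodes: list[dendropy.Node] = []
        self.parent: dict[dendropy.Node, Optional[dendropy.Node]] = {}
        self.depth: dict[dendropy.Node, int] = {}
        self.labels: dict[dendropy.Node, str] = {}
        self.leaf_by_label: dict[str, dendropy.Node] = {}
        anon = 0
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            self.nodes.append(node)
            self.parent[node] = parent
            self.depth[node] = 0 if parent is None else self.depth[parent] + 1
            name = node_name(node)
            if name is None:
                anon += 1
                name = f"node{anon}"
            self.labels[node] = name
            if node.is_leaf():
                if name in self.leaf_by_label:
                    raise ValueError(f"duplicate leaf label {name!r}")
                self.leaf_by_label[name] = node

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    @property
    def leaves(self) -> list[dendropy.Node]:
        return [n for n in self.nodes if n.is_leaf()]

    def lca(self, a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        while a is not b:
            if self.depth[a] < self.depth[b]:
                b = self.parent[b]
            else:
                a = self.parent[a]
        return a

    def is_ancestor_or_equal(self, a: dendropy.Node, b: dendropy.Node) -> bool:
        """True when ``a`` lies on the path from the root to ``b``."""
        while self.depth[b] > self.depth[a]:
            b = self.parent[b]
        return a is b

    def path_down(self, ancestor: dendropy.Node, descendant: dendropy.Node) -> list[dendropy.Node]:
        """Nodes from ``ancestor`` down to ``descendant``, inclusive."""
        path = [descendant]
        node = descendant
        while node is not ancestor:
            node = self.parent[node]
            if node is None:
                raise ValueError("ancestor does not dominate descendant")
            path.append(node)
        path.reverse()
        return path

    def ancestors_or_self(self, node: dendropy.Node) -> list[dendropy.Node]:
        out = [node]
        while self.parent[out[-1]] is not None:
            out.append(self.parent[out[-1]])
        return out
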