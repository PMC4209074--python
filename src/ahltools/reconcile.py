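"""Duplication-loss parsimony reconciliation via LCA mapping.

A rooted binary gene tree is embedded into a rooted species tree by the
classical last-common-ancestor (LCA) mapping: each gene leaf maps to its
species, each internal gene node to the LCA of its children's images.
An internal gene node is a *duplication* when it maps to the same
species node as one of its children, otherwise a *speciation*.  Losses
are read off the species-tree path spanned by each gene-tree edge: a
speciation skipping ``d`` species edges implies ``d - 1`` lost lineages,
a duplication implies ``d``, each attributed to the off-path child
subtree in which the gene lineage is absent.  LCA mapping is the unique
reconciliation minimising duplications, and it simultaneously minimises
losses; :func:`brute_force_min_reconciliation` verifies this empirically
on small instances by exhaustive enumeration of all valid mappings.

Leaf pairs whose gene-tree LCA is a speciation are orthologs; pairs
whose LCA is a duplication are paralogs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import dendropy
import pandas as pd

from .species import species_from_gene_id
from .trees import TreeIndex, node_name

SPECIATION = "SPECIATION"
DUPLICATION = "DUPLICATION"

SpeciesOf = Union[Mapping[str, str], Callable[[str], Optional[str]], None]


class ReconciliationError(ValueError):
    pass


def _resolve_species(gene_id: str, species_of: SpeciesOf,
                     species_labels: Iterable[str]) -> Optional[str]:
    if species_of is None:
        return species_from_gene_id(gene_id, codes=species_labels)
    if isinstance(species_of, Mapping):
        return species_of.get(gene_id)
    return species_of(gene_id)


def validate_gene_tree(gene_tree: dendropy.Tree) -> None:
    """Reject non-binary gene trees with actionable messages."""
    for node in gene_tree.preorder_node_iter():
        n = len(node.child_nodes())
        if node.is_leaf():
            continue
        if node is gene_tree.seed_node and n > 2:
            raise ReconciliationError(
                f"gene tree root has {n} children; the tree looks unrooted — "
                "root it on an outgroup leaf (e.g. with reroot_on_outgroup or "
                "the --outgroup option) before reconciling"
            )
        if n != 2:
            raise ReconciliationError(
                f"gene tree node {node_name(node) or '<internal>'} has {n} "
                "children; polytomies in gene trees are not supported"
            )


def reroot_on_outgroup(gene_tree: dendropy.Tree, leaf_label: str) -> dendropy.Tree:
    """Reroot a gene tree so the named leaf is sister to everything else."""
    for leaf in gene_tree.leaf_node_iter():
        if node_name(leaf) == leaf_label:
            gene_tree.reroot_at_edge(leaf.edge, update_bipartitions=False)
            gene_tree.is_rooted = True
            return gene_tree
    raise ReconciliationError(f"outgroup leaf {leaf_label!r} not found in gene tree")


def lca_map(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
            species_of: SpeciesOf = None,
            species_index: Optional[TreeIndex] = None) -> dict[dendropy.Node, dendropy.Node]:
    """LCA mapping of gene-tree nodes into the species tree.

    Gene leaves map to their species; internal nodes map bottom-up to
    the LCA of their children's images.  ``species_of`` resolves a gene
    id to a species code (mapping or callable); by default the longest
    species-tree leaf label that prefixes the gene id is used.
    """
    validate_gene_tree(gene_tree)
    sidx = species_index or TreeIndex(species_tree)
    mapping: dict[dendropy.Node, dendropy.Node] = {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            gene_id = node_name(node) or ""
            sp = _resolve_species(gene_id, species_of, sidx.leaf_by_label)
            if sp is None or sp not in sidx.leaf_by_label:
                raise ReconciliationError(
                    f"gene leaf {gene_id!r}: species {sp!r} not found in the "
                    "species tree"
                )
            mapping[node] = sidx.leaf_by_label[sp]
        else:
            children = node.child_nodes()
            image = mapping[children[0]]
            for child in children[1:]:
                image = sidx.lca(image, mapping[child])
            mapping[node] = image
    return mapping


@dataclass
class Reconciliation:
    """An LCA reconciliation with event labels and loss attributions.

    ``losses`` holds one entry per lost lineage: the gene-tree edge
    (parent, child) along which the loss is implied and the species-tree
    node (the off-path child subtree) where the lineage is absent.
    """

    gene_tree: dendropy.Tree
    species_tree: dendropy.Tree
    mapping: dict[dendropy.Node, dendropy.Node]
    events: dict[dendropy.Node, str]
    losses: list[tuple[dendropy.Node, dendropy.Node, dendropy.Node]]
    species_index: TreeIndex

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.events.values() if e == DUPLICATION)

    @property
    def n_losses(self) -> int:
        return len(self.losses)

    def duplications_by_species_node(self) -> Counter:
        """Duplication counts keyed by species-node label."""
        out: Counter = Counter()
        for g, event in self.events.items():
            if event == DUPLICATION:
                out[self.species_index.labels[self.mapping[g]]] += 1
        return out

    def losses_by_species_node(self) -> Counter:
        out: Counter = Counter()
        for _, _, snode in self.losses:
            out[self.species_index.labels[snode]] += 1
        return out


def annotate_events(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
                    mapping: dict[dendropy.Node, dendropy.Node],
                    species_index: Optional[TreeIndex] = None) -> Reconciliation:
    """Label gene-tree nodes with events and attribute losses.

    ``mapping`` must be the LCA mapping of the two trees (any mapping
    violating the ancestor constraint is rejected).
    """
    sidx = species_index or TreeIndex(species_tree)
    events: dict[dendropy.Node, str] = {}
    losses: list[tuple[dendropy.Node, dendropy.Node, dendropy.Node]] = []
    for g in gene_tree.preorder_internal_node_iter():
        children = g.child_nodes()
        for c in children:
            if not sidx.is_ancestor_or_equal(mapping[g], mapping[c]):
                raise ReconciliationError(
                    "inconsistent mapping: a gene node maps below its child"
                )
        is_dup = any(mapping[c] is mapping[g] for c in children)
        events[g] = DUPLICATION if is_dup else SPECIATION
        for c in children:
            path = sidx.path_down(mapping[g], mapping[c])
            # Species nodes at which the lineage passes through and is
            # therefore lost in every off-path child subtree.  A
            # speciation at M(g) already accounts for the split at the
            # top node; a duplicated copy must additionally be lost
            # there.
            steps = path[:-1] if is_dup else path[1:-1]
            for i, snode in enumerate(steps):
                on_path = path[path.index(snode) + 1]
                for off in snode.child_nodes():
                    if off is not on_path:
                        losses.append((g, c, off))
    return Reconciliation(
        gene_tree=gene_tree,
        species_tree=species_tree,
        mapping=mapping,
        events=events,
        losses=losses,
        species_index=sidx,
    )


def reconcile(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
              species_of: SpeciesOf = None,
              species_index: Optional[TreeIndex] = None) -> Reconciliation:
    """LCA-map a gene tree and annotate events in one call."""
    sidx = species_index or TreeIndex(species_tree)
    mapping = lca_map(gene_tree, species_tree, species_of=species_of, species_index=sidx)
    return annotate_events(gene_tree, species_tree, mapping, species_index=sidx)


@dataclass
class EventSummary:
    """Per-species-node duplication/loss counts for one clade label.

    ``per_node`` has one row per species-tree node (leaves and internal
    nodes) with columns ``node``, ``is_leaf``, ``clade``,
    ``n_duplications`` and ``n_losses``; totals equal the raw event and
    loss list lengths of the summarised reconciliations.
    """

    clade_label: str
    per_node: pd.DataFrame

    @property
    def leaf_table(self) -> pd.DataFrame:
        """Extant-species rows (the per-species layout)."""
        table = self.per_node[self.per_node.is_leaf].reset_index(drop=True)
        return table.rename(columns={"node": "species"})

    @property
    def internal_table(self) -> pd.DataFrame:
        """Ancestral-node rows (the per-internal-node layout)."""
        return self.per_node[~self.per_node.is_leaf].reset_index(drop=True)

    @property
    def total_duplications(self) -> int:
        return int(self.per_node.n_duplications.sum())

    @property
    def total_losses(self) -> int:
        return int(self.per_node.n_losses.sum())


def summarize_events(reconciliations: Union[Reconciliation, Sequence[Reconciliation]],
                     species_tree: dendropy.Tree,
                     clade_label: str = "",
                     species_index: Optional[TreeIndex] = None) -> EventSummary:
    """Bin events of one or more reconciliations onto species nodes.

    Duplications are binned at the species node each duplication gene
    node maps to; losses at their attributed species node.
    """
    if isinstance(reconciliations, Reconciliation):
        reconciliations = [reconciliations]
    sidx = species_index or TreeIndex(species_tree)
    dups: Counter = Counter()
    losses: Counter = Counter()
    for rec in reconciliations:
        dups.update(rec.duplications_by_species_node())
        losses.update(rec.losses_by_species_node())
    rows = []
    for node in sidx.nodes:
        label = sidx.labels[node]
        rows.append(
            {
                "node": label,
                "is_leaf": node.is_leaf(),
                "clade": clade_label,
                "n_duplications": int(dups.get(label, 0)),
                "n_losses": int(losses.get(label, 0)),
            }
        )
    return EventSummary(clade_label=clade_label, per_node=pd.DataFrame(rows))


ORTHOLOG = "ORTHOLOG"
PARALOG = "PARALOG"


def infer_ortholog_pairs(gene_tree: dendropy.Tree,
                         reconciliation: Reconciliation) -> list[tuple[str, str, str]]:
    """Relation of every unordered gene-leaf pair.

    A pair is orthologous when the event at its gene-tree LCA is a
    speciation, paralogous when it is a duplication.  All n(n-1)/2
    pairs are returned, each id pair in lexicographic order.
    """
    leaves_below: dict[dendropy.Node, list[str]] = {}
    pairs: list[tuple[str, str, str]] = []
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            leaves_below[node] = [node_name(node) or ""]
            continue
        children = node.child_nodes()
        relation = ORTHOLOG if reconciliation.events[node] == SPECIATION else PARALOG
        for i in range(len(children)):
            for j in range(i + 1, len(children)):
                for a in leaves_below[children[i]]:
                    for b in leaves_below[children[j]]:
                        x, y = sorted((a, b))
                        pairs.append((x, y, relation))
        merged: list[str] = []
        for c in children:
            merged.extend(leaves_below[c])
        leaves_below[node] = merged
    pairs.sort()
    return pairs


def brute_force_min_reconciliation(gene_tree: dendropy.Tree,
                                   species_tree: dendropy.Tree,
                                   species_of: SpeciesOf = None) -> tuple[int, int]:
    """Exhaustive minimum over all valid gene-to-species mappings.

    Enumerates every mapping in which each gene node maps to an
    ancestor-or-equal of the LCA of its leaf species and parents map to
    ancestors-or-equal of their children, scoring each by (duplications,
    losses); returns the lexicographic minimum.  A test oracle only:
    guarded to gene trees of <= 8 leaves and species trees of <= 5
    leaves.
    """
    validate_gene_tree(gene_tree)
    n_gene_leaves = sum(1 for _ in gene_tree.leaf_node_iter())
    sidx = TreeIndex(species_tree)
    if n_gene_leaves > 8 or len(sidx.leaf_by_label) > 5:
        raise ValueError(
            "brute_force_min_reconciliation is limited to gene trees with <= 8 "
            "leaves and species trees with <= 5 leaves"
        )

    # Lower-bound constraint: the LCA of each node's leaf species,
    # computed directly (independent of lca_map).
    constraint: dict[dendropy.Node, dendropy.Node] = {}
    postorder = list(gene_tree.postorder_node_iter())
    for node in postorder:
        if node.is_leaf():
            gene_id = node_name(node) or ""
            sp = _resolve_species(gene_id, species_of, sidx.leaf_by_label)
            if sp is None or sp not in sidx.leaf_by_label:
                raise ReconciliationError(
                    f"gene leaf {gene_id!r}: species {sp!r} not found in the species tree"
                )
            constraint[node] = sidx.leaf_by_label[sp]
        else:
            img = None
            for c in node.child_nodes():
                img = constraint[c] if img is None else sidx.lca(img, constraint[c])
            constraint[node] = img

    internal = [n for n in postorder if not n.is_leaf()]
    assign: dict[dendropy.Node, dendropy.Node] = {
        n: constraint[n] for n in postorder if n.is_leaf()
    }
    best: list[tuple[int, int]] = [(len(internal) + 1, 10 ** 9)]

    def evaluate() -> tuple[int, int]:
        d = 0
        l = 0
        for g in internal:
            c1, c2 = g.child_nodes()
            a, b1, b2 = assign[g], assign[c1], assign[c2]
            is_dup = a is b1 or a is b2 or a is not sidx.lca(b1, b2)
            d += is_dup
            for bc in (b1, b2):
                l += (sidx.depth[bc] - sidx.depth[a]) - 1 + is_dup
        return d, l

    def enumerate_from(k: int) -> None:
        if k == len(internal):
            score = evaluate()
            if score < best[0]:
                best[0] = score
            return
        g = internal[k]
        lo = None
        for c in g.child_nodes():
            lo = assign[c] if lo is None else sidx.lca(lo, assign[c])
        for candidate in sidx.ancestors_or_self(lo):
            assign[g] = candidate
            enumerate_from(k + 1)
        del assign[g]

    enumerate_from(0)
    return best[0]
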