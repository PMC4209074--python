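"""Synthetic gene families with known histories and motif-true sequences.

Two generators make the whole pipeline testable end to end with ground
truth: a continuous-time birth-death process evolves gene lineages down
a species tree (duplication rate ``lambda``, loss rate ``mu`` per unit
branch length), logging every event — observable or not — into a
:class:`TrueHistory`; and a sequence emitter realises each surviving
gene as a protein whose AT-hook and PPC cassettes follow the family's
motif grammar exactly, so a zero-noise round trip through scanning and
classification recovers the generating type for every record.

Scaffold (non-motif) residues are drawn uniformly from the 19 standard
amino acids excluding tryptophan-free constraint — more precisely, any
scaffold window that would match a cassette anchor or context signature
(RGR exact; GSKNK, GRFEIL, LRSH, FTPH at one mismatch) is rejected and
redrawn, which keeps the zero-noise round trip exact.  Optional
substitution noise is applied to the signature residues of the
cassettes only, at ``residue_mutation_rate`` per position.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import motifs
from .records import AMINO_ACIDS, ProteinRecord
from .trees import TreeIndex, node_name

ALL_TYPE_I = "ALL_TYPE_I"
ALL_TYPE_II = "ALL_TYPE_II"
MIXED = "MIXED"

_TYPE_ASSIGNMENTS = (ALL_TYPE_I, ALL_TYPE_II, MIXED)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the family simulator.

    ``duplication_rate``/``loss_rate`` are events per unit branch
    length.  ``root_copies`` ancestral lineages enter the species root;
    they model pre-divergence ancestral copies and are not logged as
    duplication events.  ``type_assignment`` controls true protein
    types (``MIXED`` draws each root lineage's base type uniformly and
    converts each Type-II gene to Type-III with
    ``type2_to_type3_prob``, emulating the repeated loss of the Type-I
    AT-hook within Clade-B).  ``residue_mutation_rate`` substitutes
    cassette signature residues i.i.d.; ``scaffold_length`` is the
    total non-motif residue budget per protein.
    """

    duplication_rate: float = 0.05
    loss_rate: float = 0.02
    root_copies: int = 1
    seed: int = 0
    type_assignment: str = MIXED
    type2_to_type3_prob: float = 0.25
    residue_mutation_rate: float = 0.0
    scaffold_length: int = 150

    def __post_init__(self) -> None:
        if not (np.isfinite(self.duplication_rate) and self.duplication_rate >= 0):
            raise ValueError("duplication_rate must be finite and >= 0")
        if not (np.isfinite(self.loss_rate) and self.loss_rate >= 0):
            raise ValueError("loss_rate must be finite and >= 0")
        if self.root_copies < 1:
            raise ValueError("root_copies must be a positive integer")
        if self.type_assignment not in _TYPE_ASSIGNMENTS:
            raise ValueError(f"type_assignment must be one of {_TYPE_ASSIGNMENTS}")
        for name in ("type2_to_type3_prob", "residue_mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.scaffold_length < 1:
            raise ValueError("scaffold_length must be positive")


@dataclass(frozen=True)
class SimEvent:
    """One logged birth-death event.

    ``branch`` names the species node at the lower end of the branch on
    which the event occurred; ``time`` is measured from the top of that
    branch; ``lineage`` identifies the affected gene lineage.
    """

    kind: str  # DUPLICATION or LOSS
    branch: str
    time: float
    lineage: int


@dataclass
class TrueHistory:
    """The simulator's complete event log — the ground truth."""

    events: list[SimEvent] = field(default_factory=list)

    def per_species_counts(self) -> dict[str, dict[str, int]]:
        """Event tallies per species branch, keyed by branch (node) label."""
        out: dict[str, dict[str, int]] = {}
        for ev in self.events:
            slot = out.setdefault(ev.branch, {"duplications": 0, "losses": 0})
            slot["duplications" if ev.kind == "DUPLICATION" else "losses"] += 1
        return out

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.events if e.kind == "DUPLICATION")

    @property
    def n_losses(self) -> int:
        return sum(1 for e in self.events if e.kind == "LOSS")

    def to_json(self) -> str:
        return json.dumps(
            {
                "events": [asdict(e) for e in self.events],
                "per_species": self.per_species_counts(),
            },
            indent=2,
            sort_keys=True,
        )


class _GeneNode:
    __slots__ = ("children", "species", "gene_id", "root_copy")

    def __init__(self, species: Optional[str] = None):
        self.children: list["_GeneNode"] = []
        self.species = species
        self.gene_id: Optional[str] = None
        self.root_copy = 0


def simulate_family(species_tree: dendropy.Tree,
                    config: SimulationConfig) -> tuple[Optional[dendropy.Tree], TrueHistory]:
    """Evolve a gene family down a species tree under birth-death.

    Each lineage duplicates at rate ``lambda`` and dies at rate ``mu``
    along every branch; at species divergences every surviving lineage
    enters all child branches.  The returned gene tree contains only
    lineages with surviving descendants; pass-through nodes with a
    single surviving child are suppressed, so the tree is binary.
    Returns ``None`` for the tree when the family goes extinct.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    sidx = TreeIndex(species_tree)
    for node in sidx.nodes:
        if node is not sidx.root and not (node.edge.length and node.edge.length > 0):
            raise ValueError(
                f"species branch above {sidx.labels[node]!r} must have positive length"
            )
    history = TrueHistory()
    lam, mu = config.duplication_rate, config.loss_rate
    total_rate = lam + mu
    lineage_counter = [0]

    def next_lineage() -> int:
        lineage_counter[0] += 1
        return lineage_counter[0]

    def at_node(snode: dendropy.Node) -> Optional[_GeneNode]:
        """A lineage arriving at the bottom of the branch into ``snode``."""
        if snode.is_leaf():
            return _GeneNode(species=sidx.labels[snode])
        surviving = []
        for child in snode.child_nodes():
            sub = on_branch(child, 0.0, next_lineage())
            if sub is not None:
                surviving.append(sub)
        if not surviving:
            return None
        if len(surviving) == 1:
            return surviving[0]  # unifurcation contraction
        node = _GeneNode()
        node.children = surviving
        return node

    def on_branch(snode: dendropy.Node, t0: float, lineage: int) -> Optional[_GeneNode]:
        """Evolve one lineage along the branch into ``snode`` from time t0."""
        length = snode.edge.length
        t = t0
        while True:
            if total_rate == 0.0:
                break
            t += rng.exponential(1.0 / total_rate)
            if t >= length:
                break
            if rng.random() < lam / total_rate:
                history.events.append(
                    SimEvent("DUPLICATION", sidx.labels[snode], t, lineage)
                )
                left = on_branch(snode, t, lineage)
                right = on_branch(snode, t, next_lineage())
                kept = [x for x in (left, right) if x is not None]
                if not kept:
                    return None
                if len(kept) == 1:
                    return kept[0]
                node = _GeneNode()
                node.children = kept
                return node
            history.events.append(SimEvent("LOSS", sidx.labels[snode], t, lineage))
            return None
        return at_node(snode)

    # Root copies speciate at the species root itself (no branch above).
    copies = []
    for i in range(config.root_copies):
        sub = at_node(sidx.root)
        if sub is not None:
            _mark_root_copy(sub, i)
            copies.append(sub)
    if not copies:
        return None, history

    root = copies[0]
    for other in copies[1:]:
        join = _GeneNode()
        join.children = [root, other]
        root = join

    _assign_gene_ids(root)
    return _to_dendropy(root), history


def _mark_root_copy(node: _GeneNode, index: int) -> None:
    node.root_copy = index
    for c in node.children:
        _mark_root_copy(c, index)


def _assign_gene_ids(root: _GeneNode) -> None:
    counters: Counter = Counter()
    for node in _postorder(root):
        if not node.children:
            counters[node.species] += 1
            node.gene_id = f"{node.species}{counters[node.species]:03d}"


def _postorder(node: _GeneNode):
    for c in node.children:
        yield from _postorder(c)
    yield node


def _to_dendropy(root: _GeneNode) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(gnode: _GeneNode) -> dendropy.Node:
        node = dendropy.Node()
        node.edge.length = 1.0
        if not gnode.children:
            node.taxon = taxa.require_taxon(label=gnode.gene_id)
            node.root_copy = gnode.root_copy
            node.true_species = gnode.species
        for c in gnode.children:
            node.add_child(build(c))
        return node

    tree.seed_node = build(root)
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Sequence emission

#: Cassette templates: (segments, signature spans are the segments
#: themselves).  Gaps inside cassettes are fixed linker residues chosen
#: outside every signature's mismatch neighbourhood.
_HOOK1_CASSETTE = motifs.AT_HOOK_CORE + "PA" + motifs.TYPE_I_CONTEXT      # RGRPAGSKNK
_HOOK2_CASSETTE = motifs.AT_HOOK_CORE + "P" + motifs.TYPE_II_CONTEXT      # RGRPRKY

#: Windows a scaffold residue may never complete.  For each signature
#: tolerated at one mismatch, its exact length-1 prefix is forbidden as
#: well: otherwise an emitted prefix such as ``LRS`` would make every
#: next residue complete ``LRSH`` within budget and the sampler could
#: not proceed.  With the prefixes excluded, at most one residue choice
#: is blocked per pattern at any step.
_FORBIDDEN = (
    (motifs.AT_HOOK_CORE, 0),
    (motifs.TYPE_I_CONTEXT, 1),
    (motifs.TYPE_I_CONTEXT[:-1], 0),
    (motifs.PPC_ANCHOR, 1),
    (motifs.PPC_ANCHOR[:-1], 0),
    (motifs.PPC_A_PREFIX, 1),
    (motifs.PPC_A_PREFIX[:-1], 0),
    (motifs.PPC_B_PREFIX, 1),
    (motifs.PPC_B_PREFIX[:-1], 0),
)


def _scaffold(rng: np.random.Generator, n: int, context: str) -> str:
    """Draw ``n`` scaffold residues that never complete a signature.

    Each residue is redrawn until no window ending at it (including
    ``context``, the already-emitted residues to its left) matches a
    forbidden pattern within its mismatch budget.
    """
    out = list(context)
    for _ in range(n):
        for attempt in range(200):
            ch = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))]
            out.append(ch)
            tail = "".join(out[-8:])
            ok = True
            for pat, budget in _FORBIDDEN:
                k = len(pat)
                if len(tail) >= k and motifs.mismatches(tail[-k:], pat) <= budget:
                    ok = False
                    break
            if ok:
                break
            out.pop()
        else:  # pragma: no cover - 20 residues always admit a choice
            raise RuntimeError("could not draw a scaffold residue")
    return "".join(out[len(context):])


def _ppc_cassette(rng: np.random.Generator, type_a: bool) -> tuple[str, list[tuple[int, int]]]:
    """A PPC domain cassette: prefix + filler + upstream tripeptide + anchor + filler.

    Returns the cassette string and the signature spans (offsets within
    the cassette) eligible for mutation.
    """
    prefix = motifs.PPC_A_PREFIX if type_a else motifs.PPC_B_PREFIX
    upstream = motifs.PPC_A_UPSTREAM if type_a else motifs.PPC_B_UPSTREAM
    fill1 = _scaffold(rng, 40, prefix)
    fill2 = _scaffold(rng, 57, motifs.PPC_ANCHOR)
    cassette = prefix + fill1 + upstream + motifs.PPC_ANCHOR + fill2
    spans = [
        (0, len(prefix)),
        (len(prefix) + 40, len(prefix) + 40 + 3),
        (len(prefix) + 43, len(prefix) + 43 + 6),
    ]
    return cassette, spans


def _emit_sequence(rng: np.random.Generator, true_type: str,
                   scaffold_length: int) -> tuple[str, list[tuple[int, int]]]:
    """Assemble one protein and the signature spans within it."""
    n_head = max(5, scaffold_length // 5)
    n_gap = 12
    n_mid = max(30, scaffold_length // 3)
    parts: list[str] = []
    spans: list[tuple[int, int]] = []
    pos = 0

    def add(segment: str, signature_spans: Optional[list[tuple[int, int]]] = None):
        nonlocal pos
        parts.append(segment)
        if signature_spans is not None:
            for a, b in signature_spans:
                spans.append((pos + a, pos + b))
        pos += len(segment)

    def add_scaffold(n: int):
        add(_scaffold(rng, n, "".join(parts)[-8:]))

    add_scaffold(n_head)
    if true_type in ("TYPE_II", "TYPE_III"):
        add(_HOOK2_CASSETTE, [(0, 3), (4, 7)])
        add_scaffold(n_gap)
    if true_type in ("TYPE_I", "TYPE_II"):
        add(_HOOK1_CASSETTE, [(0, 3), (5, 10)])
    add_scaffold(n_mid)
    cassette, ppc_spans = _ppc_cassette(rng, type_a=(true_type == "TYPE_I"))
    add(cassette, ppc_spans)
    tail = max(5, scaffold_length - n_head - n_mid - n_gap)
    add_scaffold(tail)
    return "".join(parts), spans


def _mutate(rng: np.random.Generator, sequence: str,
            spans: list[tuple[int, int]], rate: float) -> str:
    if rate <= 0.0:
        return sequence
    seq = list(sequence)
    for a, b in spans:
        for i in range(a, b):
            if rng.random() < rate:
                alternatives = AMINO_ACIDS.replace(seq[i], "")
                seq[i] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(seq)


def assign_types_and_emit_sequences(
    gene_tree: dendropy.Tree, config: SimulationConfig
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Assign a true type to every gene and emit its protein sequence.

    Returns the protein records (with intron counts: 0 for Type-I,
    1-4 for Type-II/III) and a truth table with columns ``gene_id``,
    ``species``, ``true_type`` and ``intron_count``.  Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 1])
    leaves = list(gene_tree.leaf_node_iter())

    base_types: dict[int, str] = {}
    records: list[ProteinRecord] = []
    rows = []
    for leaf in leaves:
        gene_id = node_name(leaf) or ""
        species = getattr(leaf, "true_species", None) or ""
        root_copy = getattr(leaf, "root_copy", 0)
        if config.type_assignment == ALL_TYPE_I:
            true_type = "TYPE_I"
        elif config.type_assignment == ALL_TYPE_II:
            true_type = "TYPE_II"
        else:
            if root_copy not in base_types:
                base_types[root_copy] = "TYPE_I" if rng.random() < 0.5 else "TYPE_II"
            true_type = base_types[root_copy]
        if true_type == "TYPE_II" and rng.random() < config.type2_to_type3_prob:
            true_type = "TYPE_III"

        # Resample until the clean sequence round-trips to its own type;
        # the scaffold rejection rules make failure rare, but junction
        # effects are caught here.
        for _ in range(100):
            sequence, spans = _emit_sequence(rng, true_type, config.scaffold_length)
            if _roundtrip_type(gene_id, species, sequence) == true_type:
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not realise a {true_type} sequence for {gene_id}")
        sequence = _mutate(rng, sequence, spans, config.residue_mutation_rate)

        intron_count = 0 if true_type == "TYPE_I" else int(rng.integers(1, 5))
        records.append(
            ProteinRecord(id=gene_id, species=species, sequence=sequence,
                          intron_count=intron_count)
        )
        rows.append(
            {"gene_id": gene_id, "species": species, "true_type": true_type,
             "intron_count": intron_count}
        )
    return records, pd.DataFrame(rows)


def _roundtrip_type(gene_id: str, species: str, sequence: str) -> str:
    from .classify import classify_protein

    protein = ProteinRecord(id=gene_id or "g", species=species, sequence=sequence)
    hits = motifs.scan_all(protein)
    return classify_protein(protein, hits).ahl_type.value
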