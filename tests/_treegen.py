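"""Exhaustive enumeration of small rooted binary trees for oracle tests."""

from __future__ import annotations

from itertools import combinations, product
from typing import Iterator, Sequence

from ahltools.trees import tree_from_nested


def rooted_topologies(leaves: Sequence[str]) -> Iterator[object]:
    """All rooted binary tree shapes over a labelled leaf set.

    Yields nested-tuple specs; (2n-3)!! shapes for n leaves.  Children
    are unordered: the split containing the first leaf is enumerated on
    one fixed side only.
    """
    leaves = list(leaves)
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for r in range(len(rest)):
        for left_rest in combinations(rest, r):
            left = [first, *left_rest]
            right = [x for x in rest if x not in left_rest]
            for lt in rooted_topologies(left):
                for rt in rooted_topologies(right):
                    yield (lt, rt)


def gene_tree_cases(max_leaves: int, species: Sequence[str]) -> Iterator[tuple[object, dict]]:
    """Every (gene-tree spec, species map) with 2..max_leaves leaves.

    Species labels are assigned to leaf slots in all possible ways; the
    gene ids are ``<species>_<slot>`` so ids stay unique.
    """
    for n in range(2, max_leaves + 1):
        for assignment in product(species, repeat=n):
            ids = [f"{sp}_{i}" for i, sp in enumerate(assignment)]
            species_of = dict(zip(ids, assignment))
            for shape in rooted_topologies(ids):
                yield shape, species_of


def species_topologies(used: Sequence[str]) -> Iterator[object]:
    yield from rooted_topologies(sorted(used))


def build(spec) -> object:
    return tree_from_nested(spec)


def random_shape(rng, leaf_ids: Sequence[str]):
    """One uniformly split random rooted binary shape over the leaves."""
    ids = list(leaf_ids)
    if len(ids) == 1:
        return ids[0]
    k = int(rng.integers(1, len(ids)))
    perm = list(rng.permutation(len(ids)))
    left = [ids[i] for i in perm[:k]]
    right = [ids[i] for i in perm[k:]]
    return (random_shape(rng, left), random_shape(rng, right))


def random_gene_species_case(rng, n_leaves: int, species: Sequence[str]):
    """A random gene-tree/species-tree pair for oracle spot checks."""
    assignment = [species[int(rng.integers(0, len(species)))] for _ in range(n_leaves)]
    ids = [f"{sp}_{i}" for i, sp in enumerate(assignment)]
    species_of = dict(zip(ids, assignment))
    gene_spec = random_shape(rng, ids)
    used = sorted(set(assignment))
    sp_specs = list(species_topologies(used))
    sp_spec = sp_specs[int(rng.integers(0, len(sp_specs)))]
    return gene_spec, sp_spec, species_of
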