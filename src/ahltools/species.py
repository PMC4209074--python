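"""The 19-taxon land-plant species tree and species-code table.

The tree spans the sequenced genomes in which the AHL family has been
surveyed, from the moss *Physcomitrella patens* (sister to all other
land plants here) and the lycophyte *Selaginella moellendorffii* through
grasses and a broad set of eudicots, following the Phytozome-style
species phylogeny.  Major internal nodes carry the conventional clade
letters (Em Embryophyta, T Tracheophyta, A Angiosperms, G Grasses, Eu
Eudicots, F Fabidae, NF the nitrogen-fixing clade, Mp Malpighiales, Mv
Malvidae, B Brassicaceae); the remaining binary divisions carry
descriptive clade names.  All branches have unit length.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import dendropy

from .trees import tree_from_nested

#: Species codes used in gene identifiers, mapped to binomials.
SPECIES_CODES: dict[str, str] = {
    "Al": "Arabidopsis lyrata",
    "At": "Arabidopsis thaliana",
    "Bd": "Brachypodium distachyon",
    "Bra": "Brassica rapa",
    "Cpa": "Carica papaya",
    "Cs": "Cucumis sativus",
    "Gm": "Glycine max",
    "Mdp": "Malus domestica",
    "Mes": "Manihot esculenta",
    "Mt": "Medicago truncatula",
    "Os": "Oryza sativa",
    "Pp": "Physcomitrella patens",
    "Ppa": "Prunus persica",
    "Pt": "Populus trichocarpa",
    "Rc": "Ricinus communis",
    "Sb": "Sorghum bicolor",
    "Sm": "Selaginella moellendorffii",
    "Vv": "Vitis vinifera",
    "Zm": "Zea mays",
}

# Rooted binary topology; "=X" names an internal node.
_TOPOLOGY = (
    "=Em",
    "Pp",
    (
        "=T",
        "Sm",
        (
            "=A",
            ("=G", ("=BEP", "Bd", "Os"), ("=PACMAD", "Sb", "Zm")),
            (
                "=Eu",
                "Vv",
                (
                    "=Rosids",
                    (
                        "=F",
                        ("=Mp", ("=Euphorbiaceae", "Mes", "Rc"), "Pt"),
                        (
                            "=NF",
                            ("=Fabaceae", "Mt", "Gm"),
                            ("=NFRosales", ("=Rosaceae", "Ppa", "Mdp"), "Cs"),
                        ),
                    ),
                    ("=Mv", "Cpa", ("=B", "Bra", ("=Arabidopsis", "Al", "At"))),
                ),
            ),
        ),
    ),
)


def land_plant_species_tree() -> dendropy.Tree:
    """The fixed rooted 19-taxon land-plant species tree.

    Leaves are labelled with the species codes of :data:`SPECIES_CODES`;
    internal nodes are named; every branch has unit length.
    """
    return tree_from_nested(_TOPOLOGY, branch_length=1.0)


def species_from_gene_id(gene_id: str,
                         codes: Optional[Iterable[str]] = None) -> Optional[str]:
    """Extract a species code from a gene id by longest-prefix match.

    ``Ppa0042`` resolves to ``Ppa``, not ``Pp``.  Returns ``None`` when
    no declared code is a prefix of the id.
    """
    pool = SPECIES_CODES if codes is None else list(codes)
    best = None
    for code in pool:
        if gene_id.startswith(code) and (best is None or len(code) > len(best)):
            best = code
    return best
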