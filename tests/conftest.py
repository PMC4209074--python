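import pytest

from ahltools.records import ProteinRecord
from ahltools.species import land_plant_species_tree
from ahltools.trees import TreeIndex


@pytest.fixture(scope="session")
def species_tree():
    return land_plant_species_tree()


@pytest.fixture(scope="session")
def species_index(species_tree):
    return TreeIndex(species_tree)


def protein(sequence: str, pid: str = "p1", species: str = "At", introns=None):
    return ProteinRecord(id=pid, species=species, sequence=sequence,
                         intron_count=introns)
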