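"""Core record types shared across the package.

AHL (AT-hook Motif Nuclear Localized) proteins carry one or two short
AT-hook DNA-binding motifs followed by a ~120-residue PPC (Plant and
Prokaryote Conserved, DUF296) domain.  The types here represent a protein
under analysis, a located motif instance, and the per-protein typing
verdict built from those instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

#: The 20 standard amino acids, alphabetically by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Accepted residue alphabet; X marks an unknown residue and never
#: matches any signature position.
ALPHABET = AMINO_ACIDS + "X"

_ALPHABET_SET = frozenset(ALPHABET)


class MotifClass(str, Enum):
    """Typed motif instances recognised by the scanners."""

    AT_HOOK_I = "AT_HOOK_I"
    AT_HOOK_II = "AT_HOOK_II"
    PPC_A = "PPC_A"
    PPC_B = "PPC_B"
    PPC_UNTYPED = "PPC_UNTYPED"

    @property
    def is_ppc(self) -> bool:
        return self in (MotifClass.PPC_A, MotifClass.PPC_B, MotifClass.PPC_UNTYPED)

    @property
    def is_at_hook(self) -> bool:
        return self in (MotifClass.AT_HOOK_I, MotifClass.AT_HOOK_II)


class AHLType(str, Enum):
    TYPE_I = "TYPE_I"
    TYPE_II = "TYPE_II"
    TYPE_III = "TYPE_III"
    PPC_ONLY = "PPC_ONLY"
    UNCLASSIFIED = "UNCLASSIFIED"


class Clade(str, Enum):
    A = "A"
    B = "B"
    NONE = "NONE"


#: Clade is a pure function of the type verdict: Type-I proteins form
#: Clade-A, Type-II/III proteins form Clade-B, everything else has none.
CLADE_OF_TYPE = {
    AHLType.TYPE_I: Clade.A,
    AHLType.TYPE_II: Clade.B,
    AHLType.TYPE_III: Clade.B,
    AHLType.PPC_ONLY: Clade.NONE,
    AHLType.UNCLASSIFIED: Clade.NONE,
}


class IntronStatus(str, Enum):
    CONSISTENT = "CONSISTENT"
    DISCORDANT = "DISCORDANT"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with identity and optional intron count.

    Parameters
    ----------
    id:
        Unique identifier within an input collection.
    species:
        Short species code (e.g. ``At``, ``Pp``); may be empty.
    sequence:
        Amino-acid string over the 20 standard residues plus ``X``.
    intron_count:
        Number of introns in the genomic coding sequence, if known.
    """

    id: str
    species: str
    sequence: str
    intron_count: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")
        for pos, ch in enumerate(self.sequence):
            if ch not in _ALPHABET_SET:
                raise ValueError(
                    f"protein {self.id!r}: invalid residue {ch!r} at position {pos}"
                )
        if self.intron_count is not None and self.intron_count < 0:
            raise ValueError(
                f"protein {self.id!r}: intron_count must be >= 0, got {self.intron_count}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class MotifHit:
    """A located, typed, scored motif instance on a protein.

    Coordinates are 0-based half-open; ``anchor_pos`` is the position of
    the class anchor (the Arg-Gly-Arg core for AT-hooks, the Gly-Arg-Phe-
    Glu-Ile-Leu hexapeptide for PPC domains).  ``matched`` always equals
    ``sequence[start:end]``.
    """

    start: int
    end: int
    motif_class: MotifClass = field(compare=False)
    score: float = field(compare=False)
    matched: str = field(compare=False)
    anchor_pos: int = field(compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid hit interval [{self.start}, {self.end})")
        if not (self.start <= self.anchor_pos < self.end):
            raise ValueError(
                f"anchor {self.anchor_pos} outside hit [{self.start}, {self.end})"
            )
        if len(self.matched) != self.end - self.start:
            raise ValueError("matched string length disagrees with [start, end)")

    def overlaps(self, other: "MotifHit") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class AHLClassification:
    """The per-protein verdict with its supporting evidence."""

    protein_id: str
    ahl_type: AHLType
    clade: Clade
    hits: list[MotifHit]
    intron_consistent: IntronStatus = IntronStatus.UNKNOWN
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        expected = CLADE_OF_TYPE[self.ahl_type]
        if self.clade is not expected:
            raise ValueError(
                f"{self.protein_id}: clade {self.clade.value} inconsistent with "
                f"type {self.ahl_type.value} (expected {expected.value})"
            )

    def with_intron_status(self, status: IntronStatus) -> "AHLClassification":
        return replace(self, intron_consistent=status)


@dataclass(frozen=True)
class TypeSummary:
    """Per-species type counts and percentages.

    ``n_total`` counts every classified record of the species, including
    PPC-only and unclassified ones; percentages are taken over the typed
    records only and are ``None`` when the species has no typed record.
    """

    species: str
    n_total: int
    n_type1: int
    n_type2: int
    n_type3: int
    pct_type1: Optional[float]
    pct_type2: Optional[float]
    pct_type3: Optional[float]

    def __post_init__(self) -> None:
        if self.n_type1 + self.n_type2 + self.n_type3 > self.n_total:
            raise ValueError(f"{self.species}: type counts exceed total")
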