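"""Rule-based typing of AHL proteins from motif evidence.

Land-plant AHL proteins fall into three types by domain composition,
with the PPC domain always C-terminal to the AT-hook motif(s):

* Type-I  — one Type-I AT-hook + Type-A PPC domain (Clade-A);
* Type-II — a Type-II AT-hook N-terminal to a Type-I AT-hook + Type-B
  PPC domain (Clade-B);
* Type-III — one Type-II AT-hook + Type-B PPC domain (Clade-B).

Records with a PPC domain but no AT-hook are PPC-only (the arrangement
seen in picoeukaryotes and prokaryotes); every other evidence
combination — no PPC, an untypable PPC alongside AT-hooks, AT-hooks
C-terminal to the PPC, or mixed-clade signatures — is left unclassified
with its evidence retained.

Type-I genes are intron-less while Type-II/III genes carry introns;
:func:`check_intron_consistency` flags records that contradict this
expectation without ever changing the type verdict.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

from .records import (
    CLADE_OF_TYPE,
    AHLClassification,
    AHLType,
    IntronStatus,
    MotifClass,
    MotifHit,
    ProteinRecord,
    TypeSummary,
)

SpeciesOf = Union[Mapping[str, str], Callable[[str], str]]


def classify_protein(protein: ProteinRecord, hits: Sequence[MotifHit]) -> AHLClassification:
    """Combine motif hits on one protein into a type verdict.

    The decision table is total: every hit combination yields exactly
    one verdict.  When several PPC hits are present the highest-scoring
    one (ties to leftmost) carries the typing and the record is flagged
    ``multiple_ppc``.  Only AT-hooks wholly N-terminal to the chosen PPC
    domain participate in typing; C-terminal AT-hooks are flagged.
    """
    for h in hits:
        if h.end > len(protein.sequence):
            raise ValueError(
                f"{protein.id}: hit [{h.start}, {h.end}) outside sequence of "
                f"length {len(protein.sequence)}"
            )

    flags: list[str] = []
    ppc_hits = [h for h in hits if h.motif_class.is_ppc]
    hook_hits = [h for h in hits if h.motif_class.is_at_hook]

    if not ppc_hits:
        verdict = AHLType.UNCLASSIFIED
    else:
        ppc = max(ppc_hits, key=lambda h: (h.score, -h.start))
        if len(ppc_hits) > 1:
            flags.append("multiple_ppc")
        if not hook_hits:
            verdict = AHLType.PPC_ONLY
        elif ppc.motif_class is MotifClass.PPC_UNTYPED:
            flags.append("untyped_ppc")
            verdict = AHLType.UNCLASSIFIED
        else:
            n_term = [h for h in hook_hits if h.end <= ppc.start]
            if len(n_term) < len(hook_hits):
                flags.append("c_terminal_at_hook")
            if not n_term:
                verdict = AHLType.UNCLASSIFIED
            else:
                has_i = any(h.motif_class is MotifClass.AT_HOOK_I for h in n_term)
                has_ii = any(h.motif_class is MotifClass.AT_HOOK_II for h in n_term)
                if ppc.motif_class is MotifClass.PPC_A:
                    if has_i and not has_ii:
                        verdict = AHLType.TYPE_I
                    else:
                        flags.append("mixed_clade_evidence")
                        verdict = AHLType.UNCLASSIFIED
                else:  # PPC_B
                    if has_i and has_ii:
                        verdict = AHLType.TYPE_II
                    elif has_ii:
                        verdict = AHLType.TYPE_III
                    else:
                        flags.append("mixed_clade_evidence")
                        verdict = AHLType.UNCLASSIFIED

    return AHLClassification(
        protein_id=protein.id,
        ahl_type=verdict,
        clade=CLADE_OF_TYPE[verdict],
        hits=sorted(hits),
        flags=tuple(flags),
    )


def check_intron_consistency(classification: AHLClassification,
                             intron_count: Optional[int]) -> AHLClassification:
    """Annotate a verdict with its intron-count consistency.

    Type-I genes are expected intron-less; Type-II/III genes are
    expected to carry at least one intron.  Returns an updated copy; the
    type verdict itself never changes.
    """
    if intron_count is not None and intron_count < 0:
        raise ValueError(f"intron_count must be >= 0, got {intron_count}")
    t = classification.ahl_type
    if intron_count is None or t not in (AHLType.TYPE_I, AHLType.TYPE_II, AHLType.TYPE_III):
        status = IntronStatus.UNKNOWN
    elif (t is AHLType.TYPE_I) == (intron_count == 0):
        status = IntronStatus.CONSISTENT
    else:
        status = IntronStatus.DISCORDANT
    return classification.with_intron_status(status)


def summarize_types(classifications: Iterable[AHLClassification],
                    species_of: SpeciesOf) -> list[TypeSummary]:
    """Per-species type counts and percentages.

    ``species_of`` maps protein ids to species codes (mapping or
    callable); every classified protein must be mapped.  Percentages are
    taken over the typed (I/II/III) records and are ``None`` for species
    without any; the summary is sorted by species code.
    """
    lookup = species_of.__getitem__ if isinstance(species_of, Mapping) else species_of
    counts: dict[str, dict[AHLType, int]] = defaultdict(lambda: defaultdict(int))
    totals: dict[str, int] = defaultdict(int)
    for cls in classifications:
        species = lookup(cls.protein_id)
        if species is None:
            raise KeyError(f"no species mapping for protein {cls.protein_id!r}")
        totals[species] += 1
        counts[species][cls.ahl_type] += 1

    summaries = []
    for species in sorted(totals):
        n1 = counts[species][AHLType.TYPE_I]
        n2 = counts[species][AHLType.TYPE_II]
        n3 = counts[species][AHLType.TYPE_III]
        typed = n1 + n2 + n3
        pct = (lambda n: 100.0 * n / typed) if typed else (lambda n: None)
        summaries.append(
            TypeSummary(
                species=species,
                n_total=totals[species],
                n_type1=n1,
                n_type2=n2,
                n_type3=n3,
                pct_type1=pct(n1),
                pct_type2=pct(n2),
                pct_type3=pct(n3),
            )
        )
    return summaries
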