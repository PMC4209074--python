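"""Reading and writing the pipeline's standard formats.

FASTA goes through Biopython; GFF3 through gffutils; tabular outputs
are TSV with a leading ``#`` provenance comment line, readable back
with pandas.  FASTA description lines may carry an explicit
``species=XX`` token; otherwise the species code is recovered from the
identifier prefix.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .records import AHLClassification, MotifClass, MotifHit, ProteinRecord, TypeSummary
from .species import species_from_gene_id

PathLike = Union[str, Path]

HITS_COLUMNS = [
    "protein_id", "motif_class", "start0", "end0", "start1", "end1",
    "anchor_pos", "score", "matched",
]


def _header(config_hash: str = "-") -> str:
    return f"# ahltools {__version__} config={config_hash}\n"


def read_fasta(path: PathLike) -> list[ProteinRecord]:
    """Read protein records; description may carry ``species=XX``."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        species = ""
        for token in rec.description.split():
            if token.startswith("species="):
                species = token.split("=", 1)[1]
        if not species:
            species = species_from_gene_id(rec.id) or ""
        records.append(ProteinRecord(id=rec.id, species=species, sequence=str(rec.seq)))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: PathLike) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=f"species={r.species}")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def write_hits_tsv(hits_by_protein: Iterable[tuple[str, Sequence[MotifHit]]],
                   path: PathLike, config_hash: str = "-") -> None:
    """Write hits as TSV with both 0-based half-open and 1-based
    inclusive coordinate columns."""
    rows = []
    for protein_id, hits in hits_by_protein:
        for h in hits:
            rows.append(
                {
                    "protein_id": protein_id,
                    "motif_class": h.motif_class.value,
                    "start0": h.start,
                    "end0": h.end,
                    "start1": h.start + 1,
                    "end1": h.end,
                    "anchor_pos": h.anchor_pos,
                    "score": h.score,
                    "matched": h.matched,
                }
            )
    frame = pd.DataFrame(rows, columns=HITS_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        frame.to_csv(fh, sep="\t", index=False)


def read_hits_tsv(path: PathLike) -> dict[str, list[MotifHit]]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, list[MotifHit]] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(str(row.protein_id), []).append(
            MotifHit(
                start=int(row.start0),
                end=int(row.end0),
                motif_class=MotifClass(row.motif_class),
                score=float(row.score),
                matched=str(row.matched),
                anchor_pos=int(row.anchor_pos),
            )
        )
    return out


def write_classifications_tsv(classifications: Iterable[AHLClassification],
                              path: PathLike, config_hash: str = "-") -> None:
    rows = []
    for c in classifications:
        evidence = ";".join(
            f"{h.motif_class.value}@{h.start}-{h.end}" for h in c.hits
        )
        rows.append(
            {
                "protein_id": c.protein_id,
                "ahl_type": c.ahl_type.value,
                "clade": c.clade.value,
                "intron_consistent": c.intron_consistent.value,
                "flags": ";".join(c.flags),
                "evidence": evidence,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["protein_id", "ahl_type", "clade", "intron_consistent", "flags", "evidence"],
    )
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        frame.to_csv(fh, sep="\t", index=False)


def write_type_summary_tsv(summaries: Iterable[TypeSummary], path: PathLike,
                           config_hash: str = "-") -> None:
    rows = []
    for s in summaries:
        fmt = lambda p: "" if p is None else f"{p:.1f}"
        rows.append(
            {
                "species": s.species,
                "n_total": s.n_total,
                "n_type1": s.n_type1,
                "n_type2": s.n_type2,
                "n_type3": s.n_type3,
                "pct_type1": fmt(s.pct_type1),
                "pct_type2": fmt(s.pct_type2),
                "pct_type3": fmt(s.pct_type3),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["species", "n_total", "n_type1", "n_type2", "n_type3",
                 "pct_type1", "pct_type2", "pct_type3"],
    )
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        frame.to_csv(fh, sep="\t", index=False)


def read_intron_tsv(path: PathLike) -> dict[str, int]:
    """Two-column TSV (gene_id, intron_count), with or without header."""
    frame = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if list(frame.iloc[0]) and not frame.iloc[0, 1].lstrip("-").isdigit():
        frame = frame.iloc[1:]
    out = {}
    for _, (gene_id, count) in frame.iterrows():
        out[str(gene_id)] = int(count)
    return out


def intron_counts_from_gff3(path: PathLike) -> dict[str, int]:
    """Intron counts per mRNA from GFF3: CDS segments per mRNA minus 1.

    Counts introns within the coding sequence only, keyed by mRNA id.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out: dict[str, int] = {}
    for mrna in db.features_of_type("mRNA"):
        n_cds = sum(1 for _ in db.children(mrna, featuretype="CDS"))
        out[mrna.id] = max(0, n_cds - 1)
    return out


def read_species_map(path: PathLike) -> dict[str, str]:
    """Two-column TSV (gene_id, species_code)."""
    frame = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    return {str(g): str(s) for g, s in zip(frame[0], frame[1])}


def write_reconciliation_json(reconciliation, path: PathLike,
                              config_hash: str = "-") -> None:
    from .trees import node_name

    rec = reconciliation
    sidx = rec.species_index
    gene_labels = {}
    for i, node in enumerate(rec.gene_tree.preorder_node_iter()):
        gene_labels[node] = node_name(node) or f"g{i}"
    payload = {
        "_meta": {"tool": f"ahltools {__version__}", "config": config_hash},
        "mapping": {gene_labels[g]: sidx.labels[s] for g, s in rec.mapping.items()},
        "events": {gene_labels[g]: e for g, e in rec.events.items()},
        "losses": [
            {"gene_edge": [gene_labels[g], gene_labels[c]], "species_node": sidx.labels[s]}
            for g, c, s in rec.losses
        ],
        "n_duplications": rec.n_duplications,
        "n_losses": rec.n_losses,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_event_summary_tsvs(summary, leaf_path: PathLike, internal_path: PathLike,
                             config_hash: str = "-") -> None:
    with open(leaf_path, "w") as fh:
        fh.write(_header(config_hash))
        summary.leaf_table.drop(columns=["is_leaf"]).to_csv(fh, sep="\t", index=False)
    with open(internal_path, "w") as fh:
        fh.write(_header(config_hash))
        summary.internal_table.drop(columns=["is_leaf"]).to_csv(fh, sep="\t", index=False)
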