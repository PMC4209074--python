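"""Signature-based scanning of AT-hook motifs and PPC domains.

The scanners implement the consensus grammar of land-plant AHL proteins:

* Both AT-hook types share an exact Arg-Gly-Arg (RGR) core.  A core is a
  Type-I AT-hook when the Gly-Ser-Lys-Asn-Lys (GSKNK) consensus begins
  within ``window`` residues downstream of the core (one mismatch
  tolerated), and a Type-II AT-hook when instead an exact Arg-Lys-Tyr
  (RKY) occurs in that span.  A core with neither context is not a hit.
* PPC domains anchor on the conserved Gly-Arg-Phe-Glu-Ile-Leu (GRFEIL)
  hexapeptide (one mismatch tolerated) and extend ``span`` residues to
  each side, clipped to the sequence, for a reported domain of roughly
  120 residues.  The domain is Type-A when the tripeptide immediately
  upstream of the anchor matches Thr-Lys-His (TKH) or the domain window
  begins with Leu-Arg-Ser-His (LRSH), and Type-B likewise via
  Thr-Tyr-Glu (TYE) / Phe-Thr-Pro-His (FTPH), each at one mismatch.
  When both or neither typing rule fires the hit is left untyped rather
  than tie-broken; downstream classification surfaces the ambiguity.

Matching thresholds: exact for 3-mers on the primary path (RGR, RKY),
one mismatch for signatures of length >= 4 and for the TKH/TYE upstream
context.  ``X`` never matches a signature position.

Overlapping candidate hits within one scan are resolved greedily by
score, then by leftmost start; returned hits never overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np

from .records import AMINO_ACIDS, MotifClass, MotifHit, ProteinRecord

# Consensus signature strings of the family.
AT_HOOK_CORE = "RGR"
TYPE_I_CONTEXT = "GSKNK"
TYPE_II_CONTEXT = "RKY"
PPC_ANCHOR = "GRFEIL"
PPC_A_PREFIX = "LRSH"
PPC_B_PREFIX = "FTPH"
PPC_A_UPSTREAM = "TKH"
PPC_B_UPSTREAM = "TYE"

DEFAULT_AT_HOOK_WINDOW = 10
DEFAULT_PPC_SPAN = 60
DEFAULT_PSEUDOCOUNT = 0.01

LOG2_20 = math.log2(20.0)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def mismatches(window: str, signature: str) -> int:
    """Count mismatching positions between equal-length strings.

    ``X`` in the scanned window never matches, and signatures contain no
    ``X``, so plain inequality is the correct test.
    """
    if len(window) != len(signature):
        raise ValueError("window and signature lengths differ")
    return sum(a != b for a, b in zip(window, signature))


def _find_approx(seq: str, signature: str, max_mm: int,
                 start: int = 0, stop: Optional[int] = None) -> Iterator[tuple[int, int]]:
    """Yield (position, mismatch count) of signature matches.

    ``start``/``stop`` bound the *starting* position of the match.
    """
    k = len(signature)
    if stop is None:
        stop = len(seq) - k
    stop = min(stop, len(seq) - k)
    for p in range(max(start, 0), stop + 1):
        mm = mismatches(seq[p:p + k], signature)
        if mm <= max_mm:
            yield p, mm


def _select_nonoverlapping(candidates: list[MotifHit]) -> list[MotifHit]:
    """Greedy overlap resolution: best score first, ties to leftmost."""
    chosen: list[MotifHit] = []
    for hit in sorted(candidates, key=lambda h: (-h.score, h.start, h.end)):
        if not any(hit.overlaps(c) for c in chosen):
            chosen.append(hit)
    chosen.sort(key=lambda h: (h.start, h.end))
    return chosen


def scan_at_hooks(protein: ProteinRecord, window: int = DEFAULT_AT_HOOK_WINDOW) -> list[MotifHit]:
    """Locate and type AT-hook motifs on a protein.

    Parameters
    ----------
    protein:
        Validated protein record.
    window:
        Search span (in residues) downstream of the RGR core within
        which the typing context must begin; must be >= 5.

    Returns
    -------
    list of MotifHit
        Non-overlapping hits sorted by start.  Each hit spans from the
        RGR core through the end of its typing context, with the anchor
        at the core start.
    """
    if window < 5:
        raise ValueError(f"window must be >= 5, got {window}")
    seq = protein.sequence
    candidates: list[MotifHit] = []
    for core, _ in _find_approx(seq, AT_HOOK_CORE, 0):
        # Context may begin at any of the `window` positions following
        # the core's last arginine.
        ctx_lo = core + 3
        ctx_hi = core + 2 + window
        hit = None
        for p, mm in _find_approx(seq, TYPE_I_CONTEXT, 1, ctx_lo, ctx_hi):
            hit = MotifHit(
                start=core,
                end=p + len(TYPE_I_CONTEXT),
                motif_class=MotifClass.AT_HOOK_I,
                score=float(len(AT_HOOK_CORE) + len(TYPE_I_CONTEXT) - mm),
                matched=seq[core:p + len(TYPE_I_CONTEXT)],
                anchor_pos=core,
            )
            break
        if hit is None:
            for p, _ in _find_approx(seq, TYPE_II_CONTEXT, 0, ctx_lo, ctx_hi):
                hit = MotifHit(
                    start=core,
                    end=p + len(TYPE_II_CONTEXT),
                    motif_class=MotifClass.AT_HOOK_II,
                    score=float(len(AT_HOOK_CORE) + len(TYPE_II_CONTEXT)),
                    matched=seq[core:p + len(TYPE_II_CONTEXT)],
                    anchor_pos=core,
                )
                break
        if hit is not None:
            candidates.append(hit)
    return _select_nonoverlapping(candidates)


def scan_ppc(protein: ProteinRecord, span: int = DEFAULT_PPC_SPAN) -> list[MotifHit]:
    """Locate and type PPC (DUF296) domains on a protein.

    Parameters
    ----------
    protein:
        Validated protein record.
    span:
        Domain window radius around the GRFEIL anchor, in residues;
        must be >= 60 so that the reported domain approaches the
        canonical ~120-residue extent.

    Returns
    -------
    list of MotifHit
        Non-overlapping hits sorted by start; one candidate per anchor.
    """
    if span < 60:
        raise ValueError(f"span must be >= 60, got {span}")
    seq = protein.sequence
    candidates: list[MotifHit] = []
    for p, mm in _find_approx(seq, PPC_ANCHOR, 1):
        start = max(0, p - span)
        end = min(len(seq), p + len(PPC_ANCHOR) + span)
        upstream = seq[p - 3:p] if p >= 3 else ""
        prefix = seq[start:start + 4]
        evidence_a = (len(upstream) == 3 and mismatches(upstream, PPC_A_UPSTREAM) <= 1) or (
            len(prefix) == 4 and mismatches(prefix, PPC_A_PREFIX) <= 1
        )
        evidence_b = (len(upstream) == 3 and mismatches(upstream, PPC_B_UPSTREAM) <= 1) or (
            len(prefix) == 4 and mismatches(prefix, PPC_B_PREFIX) <= 1
        )
        if evidence_a and not evidence_b:
            motif_class = MotifClass.PPC_A
        elif evidence_b and not evidence_a:
            motif_class = MotifClass.PPC_B
        else:
            # Both or neither typing rule fired: ambiguity is surfaced,
            # never silently tie-broken.
            motif_class = MotifClass.PPC_UNTYPED
        score = float(len(PPC_ANCHOR) - mm + (motif_class is not MotifClass.PPC_UNTYPED))
        candidates.append(
            MotifHit(
                start=start,
                end=end,
                motif_class=motif_class,
                score=score,
                matched=seq[start:end],
                anchor_pos=p,
            )
        )
    return _select_nonoverlapping(candidates)


def scan_all(protein: ProteinRecord, window: int = DEFAULT_AT_HOOK_WINDOW,
             span: int = DEFAULT_PPC_SPAN) -> list[MotifHit]:
    """Run both scanners and return all hits sorted by start."""
    hits = scan_at_hooks(protein, window=window) + scan_ppc(protein, span=span)
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


@dataclass
class MotifProfile:
    """A position-frequency profile over aligned motif instances.

    ``freqs`` has shape (n_columns, 20) over :data:`AMINO_ACIDS`; each
    row sums to 1.  ``conservation`` holds per-column information
    content, ``log2(20) - H(column)`` in bits, in [0, log2(20)].
    """

    freqs: np.ndarray
    n_sequences: int
    alphabet: str = AMINO_ACIDS
    conservation: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != len(self.alphabet):
            raise ValueError("freqs must have shape (n_columns, 20)")
        sums = self.freqs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each profile column must sum to 1")
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(self.freqs > 0, self.freqs * np.log2(self.freqs), 0.0)
        entropy = -plogp.sum(axis=1)
        self.conservation = LOG2_20 - entropy

    @property
    def n_columns(self) -> int:
        return self.freqs.shape[0]


def build_profile(instances: Sequence[str]) -> MotifProfile:
    """Build a position-frequency profile from aligned motif strings.

    All instances must be non-empty, equal length, and drawn from the
    20-letter amino-acid alphabet.
    """
    if len(instances) == 0:
        raise ValueError("at least one instance is required")
    length = len(instances[0])
    if length == 0:
        raise ValueError("instances must be non-empty")
    counts = np.zeros((length, len(AMINO_ACIDS)), dtype=float)
    for inst in instances:
        if len(inst) != length:
            raise ValueError("instances must all have the same length")
        for j, ch in enumerate(inst):
            idx = _AA_INDEX.get(ch)
            if idx is None:
                raise ValueError(f"invalid residue {ch!r} in instance {inst!r}")
            counts[j, idx] += 1.0
    return MotifProfile(freqs=counts / len(instances), n_sequences=len(instances))


def score_window(window: str, profile: MotifProfile,
                 background: Optional[Mapping[str, float] | Sequence[float]] = None,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Log-odds score of a window against a profile.

    Computes ``sum_j log2(f'_j(window_j) / background(window_j))`` where
    ``f' = (f + a) / (1 + 20 a)`` regularizes column frequencies with
    pseudocount ``a`` per residue.  The background defaults to uniform
    1/20 and must sum to 1.  Higher scores indicate better matches.
    """
    if len(window) != profile.n_columns:
        raise ValueError(
            f"window length {len(window)} != profile columns {profile.n_columns}"
        )
    if background is None:
        bg = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    elif isinstance(background, Mapping):
        bg = np.array([background[aa] for aa in AMINO_ACIDS], dtype=float)
    else:
        bg = np.asarray(background, dtype=float)
    if bg.shape != (len(AMINO_ACIDS),) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("background must assign the 20 residues frequencies summing to 1")
    norm = 1.0 + len(AMINO_ACIDS) * pseudocount
    score = 0.0
    for j, ch in enumerate(window):
        idx = _AA_INDEX.get(ch)
        if idx is None:
            raise ValueError(f"invalid residue {ch!r} at window position {j}")
        f = (profile.freqs[j, idx] + pseudocount) / norm
        score += math.log2(f / bg[idx])
    return score
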