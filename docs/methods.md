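# Methods

## Motif grammar and scanning

AHL proteins are recognised from primary sequence alone, using the
consensus signatures that define the family's two AT-hook types and two
PPC-domain types.

**AT-hook motifs.** Both types share an exact Arg-Gly-Arg (`RGR`) core.
After each core, a downstream window of `window` residues (default 10,
configurable; the consensus sits directly at the carboxyl side of the
core, and 10 residues comfortably cover the conserved span) is searched
for the typing context: `GSKNK` at up to one mismatch makes the hit
Type-I; otherwise an exact `RKY` makes it Type-II; a core with neither
context is not reported. The reported hit runs from the core through the
end of its context, with the anchor at the core.

**PPC domains.** The scanner anchors on the `GRFEIL` hexapeptide at up to
one mismatch and reports a window of `span` residues (default 60) on each
side of the anchor, clipped at the sequence ends — about 120 residues, the
canonical extent of the domain. Typing evidence for Type-A is an upstream
`TKH` tripeptide immediately before the anchor (≤ 1 mismatch) or a window
beginning with `LRSH` (≤ 1 mismatch); Type-B likewise via `TYE`/`FTPH`.
When both or neither fire, the hit is reported untyped: the two clades are
disjoint, so ambiguous evidence is surfaced rather than tie-broken, and
classification downstream treats such records as unclassifiable.

**Matching thresholds.** Signatures of length ≥ 4 tolerate one mismatch;
the core and `RKY` are exact; the upstream tripeptides `TKH`/`TYE` tolerate
one mismatch because they are qualified consensus ("generally") rather
than invariant. `X` (unknown residue) never matches a signature position.
These budgets accept the moderate conservation real instances show while
keeping scanning deterministic.

Overlapping candidates within one scan are resolved greedily by score
(signature length minus mismatches, plus one for a typed PPC), ties to the
leftmost start; reported hits never overlap. Coordinates are 0-based
half-open internally; TSV output adds 1-based inclusive columns.

**Profiles.** `build_profile` turns equal-length aligned instances into
per-column relative frequencies over the 20 standard residues; column
conservation is `log2(20) − H` bits (Shannon entropy), so a single-residue
column scores log2(20) ≈ 4.32 bits and a uniform column 0. `score_window`
is a log-odds score `Σ_j log2(f'_j(w_j)/b(w_j))` with per-residue
pseudocount regularisation `f' = (f + a)/(1 + 20a)` (default a = 0.01)
against a background `b` (default uniform 1/20). It exists for ranking and
sensitive scanning experiments; the primary scanners are threshold-based
and do not depend on it.

## Classification

The decision table is total. A record needs a PPC hit to be anything but
unclassified; a PPC hit with no AT-hook at all is PPC-only (the
architecture seen in prokaryotes and picoeukaryotic algae). When several
PPC hits are present — the family's proteins carry one domain, so this
indicates a scanning artefact or an unusual protein — the highest-scoring
hit carries the typing and the record is flagged. Only AT-hooks wholly
N-terminal to the chosen PPC domain participate, since the domain is
always C-terminal to the motifs in genuine AHLs; records whose only hooks
are C-terminal, whose PPC is untyped, or whose hook types conflict with
the PPC type (e.g. Type-I hook with a Type-B domain) are unclassified with
the evidence retained. Extra hooks beyond the defining set do not change
the verdict: typing uses presence/absence of each hook type, not counts.

Intron consistency (Type-I intron-less; Type-II/III with ≥ 1 intron) is an
annotation, never a veto: `CONSISTENT`/`DISCORDANT` when a count is known,
`UNKNOWN` otherwise. Counts come from a two-column TSV or from GFF3 as CDS
segments per mRNA minus one — introns within the coding region only.

Per-species summaries count every classified record in `n_total` but take
percentages over the typed (I/II/III) records, blank when a species has
none.

## Species tree and reconciliation

The built-in species tree covers the 19 sequenced land-plant genomes in
which the family has been surveyed, with unit branch lengths and the moss
*Physcomitrella patens* sister to all other taxa, *Selaginella* sister to
the angiosperms, and the conventional grass/eudicot structure below that
(Vitis basal in the eudicots; fabids vs malvids). Ten internal nodes carry
their conventional clade letters (Em, T, A, G, Eu, F, NF, Mp, Mv, B); the
remaining eight binary divisions carry descriptive names.

Gene trees must arrive rooted and binary. No automatic rerooting is
performed — reconciliation results depend on the root, and a silent
midpoint root would hide that — but `reroot_on_outgroup` (CLI
`--outgroup`) reroots on a named leaf. Internal polytomies are rejected.
Support values and branch lengths in input Newick are tolerated and
ignored. Species assignment of gene leaves uses longest-prefix matching
against the species-code table (`Ppa…` is *Prunus persica*, not
*Physcomitrella* + `a…`), overridable by an explicit two-column map.

LCA mapping is computed bottom-up; events and losses follow the standard
duplication–loss parsimony reading (see README for the formulas). Losses
are attributed to the species node of the off-path child subtree at each
skipped step. On a binary species tree this is exactly one loss per
skipped edge; if a species-tree polytomy is supplied, one loss is recorded
per absent child subtree at each step — the natural generalisation of the
attribution rule, though note that under a "soft polytomy" reading this
overstates certainty about losses.

Summaries bin duplications at the species node each duplication maps to
and losses at their attributed node; the per-extant-species table and the
per-internal-node table are two views of the same conserved totals. A
duplication appears in the per-species table only when it maps to that
leaf; duplications at ancestral nodes appear in the internal-node table.

`brute_force_min_reconciliation` enumerates every mapping that respects
the leaf-LCA lower bound and parent/child ancestry, scoring duplications
(a node mapping onto a child's image, or strictly above its children's
LCA) and losses per edge as `d − 1 + [duplication]`, and returns the
lexicographic (duplications, losses) minimum. It is deliberately
independent of the LCA construction and guarded to ≤ 8 gene leaves / ≤ 5
species, and exists only as a test oracle.

Equally-parsimonious alternatives do not arise: the LCA mapping is the
unique minimum-duplication reconciliation, and it simultaneously minimises
losses — the acceptance suite verifies this empirically on an exhaustive
frontier of small instances.

## Simulator

`simulate_family` runs a continuous-time birth–death process per lineage
down each species branch: exponential waiting times at total rate λ + μ,
a duplication splitting the lineage in place, a loss terminating it; at
each species divergence every surviving lineage enters all child branches.
Only lineages with surviving descendants appear in the output gene tree;
pass-through nodes are contracted so the tree is binary. The complete
event log — including unobservable events — is returned as the true
history, with each event tagged by the species branch (named by its lower
node), the time along it, and the lineage. `root_copies` ancestral
lineages (default 1) enter the root and are joined under pseudo-root
nodes; they model pre-divergence ancestral copies and are not logged as
duplications.

Default rates λ = 0.05, μ = 0.02 per unit branch produce families of a few
tens of genes on the 19-taxon tree — the scale observed for this family in
real genomes. Rates are configuration, not constants.

With μ = 0 every true duplication has surviving descendants on both sides,
so it appears as a gene-tree node mapping to the branch's lower species
node: inferred per-node duplication counts must equal the logged truth
exactly, with zero losses. With μ > 0 the true history restricted to
surviving lineages is itself a valid reconciliation, so the parsimony
minimum can never exceed the true counts — both facts are exercised as
acceptance tests.

**Sequence emission.** Each gene receives a true type (`ALL_TYPE_I`,
`ALL_TYPE_II`, or `MIXED`, which draws each root lineage's base type
uniformly from Type-I/Type-II and converts each Type-II gene to Type-III
with `type2_to_type3_prob`, default 0.25 — mimicking the repeated loss of
the Type-I hook within Clade-B). Sequences are assembled as scaffold +
cassettes in the family's N-to-C order (Type-II hook, Type-I hook, PPC
domain, as the type requires). Scaffold residues are drawn uniformly over
the 20 standard amino acids with rejection of any window that would
complete a signature (`RGR` exact; `GSKNK`, `GRFEIL`, `LRSH`, `FTPH` at
one mismatch, plus their exact length−1 prefixes so the sampler always has
≥ 19 admissible residues). Each clean sequence is verified to round-trip
through scanning and classification to its own type before optional noise
is applied; substitution noise at `residue_mutation_rate` then hits the
cassette signature residues only. Intron counts are 0 for Type-I and
uniform on {1,…,4} for Type-II/III. `scaffold_length` (default 150)
fixes the non-motif budget, giving proteins of roughly 250–300 residues.

All randomness flows from a single integer seed through one numpy
generator per operation, so outputs are byte-identical across reruns.

**What the simulator does not emulate.** Motifs mutate i.i.d., not along
the tree; there is no nucleotide/codon level, no alignment uncertainty, no
gene-tree estimation error, no rate variation across branches, and
scaffold composition is uniform rather than realistic. Passing tests
therefore demonstrate correctness of the scanning/classification/
reconciliation machinery under the stated grammar and model — not
robustness to phylogenetic inference error or to divergence far from the
consensus signatures.

## Problem sizes in the validation suite

The oracle-equivalence check is exhaustive over all rooted binary gene
trees with up to 5 leaves drawn from up to 3 species, against every rooted
species topology on the species used (~60,000 brute-forced instances),
plus 300 seeded random 6-leaf/4-species cases. Recovery and bound checks
use 200 simulated families per regime and 500 proteins per noise level.
These sizes give exhaustive coverage where enumeration is cheap and tight
Monte-Carlo coverage elsewhere while keeping the whole suite fast enough
to run on every change.

## Known limitations

- No duplication–transfer–loss model and no Notung-style
  rearrangement/threshold editing of weakly supported edges.
- Subfamily-level assignment (A1–A5, B1–B4) requires an inferred
  phylogeny and is out of scope.
- The scanners are consensus/regex-based, not HMMs; remote homologs whose
  signatures drift beyond one mismatch are missed by design (the
  log-odds profile scorer is available for more sensitive experiments).
- GFF3 intron counting assumes CDS features carry `Parent` links to mRNA
  features.
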