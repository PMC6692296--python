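# Methods

## The comparison model

Two strains' folded RNA regions are comparable site-by-site once their
structures are placed in a common column frame. The unit of comparison is
the *homologous base-pair site*: a pair of alignment columns (ci, cj) such
that at least one strain has a base pair whose endpoints occupy those
columns. At each site the two strains present an ordered residue pair
(5′ partner, 3′ partner), classified as

| category   | definition                                   |
|------------|----------------------------------------------|
| canonical  | A–U, U–A, G–C, C–G                           |
| wobble     | G·U, U·G                                     |
| mismatch   | any other residue pair, incl. anything with N |
| gapped     | either side is `-`                           |
| unpaired   | the strain has no pair at this site          |

Canonical and wobble states are *pairing-capable*. The change between two
states is then, in order of precedence:

1. **identical** — same residues on both sides *and* the same pairing
   status. Identical residues where only one strain actually pairs are not
   an identity (see pairing loss/gain below).
2. **indel** — a gap on either side of either state.
3. **CBC** — both states pairing-capable, both residues differ. This
   includes changes whose endpoint is a wobble (A–U → U·G): the defining
   property — both partners change, pairing retained — is satisfied.
4. **HCBC** — both states pairing-capable, exactly one residue differs.
5. **pairing lost / gained** — pairing-capable on exactly one side
   (direction named from strain A to strain B).
6. **substitution-in-mismatch** — neither side pairing-capable, residues
   differ.

N never counts as pairing-capable: an ambiguous read must not manufacture
compensatory evidence. The classifier is total on valid states, symmetric
under exchanging the strains except for the lost ↔ gained swap, and is
verified in the test suite against an independently written truth table
over all 625 ordered residue-pair combinations.

## Alignment

Column correspondence comes either from a user-supplied alignment (aligned
FASTA; the loader rejects `.` as a gap to avoid confusion with dot-bracket)
or from the built-in global aligner: Needleman–Wunsch with affine gaps in
Gotoh's three-state formulation, plus a constant *structure bonus* added to
the substitution score whenever the two aligned positions are both paired
in their own structures. Defaults: match +2, mismatch −1, gap open −4, gap
extend −1, bonus +1; a gap of length L costs `open + L·extend`. The
defaults keep conserved helices ungapped while letting sequence signal
dominate elsewhere; all five numbers are exposed in `ScoringConfig`.
Tie-breaking is fixed (diagonal over up over left, and M > X > Y among DP
states), so alignments are byte-reproducible. The DP is verified against
exhaustive enumeration of all global alignments on instances up to ~7 nt.

Families of more than two strains are compared star-wise: every strain is
aligned to one reference (default: the first input) and all pair sites are
expressed in reference coordinates, so one region window applies uniformly
and the count matrices are symmetric by construction. A base pair that does
not anchor to reference coordinates (both endpoints fall in
reference-gapped columns) is counted as an indel-class site and excluded
from any region-restricted count, since it has no reference coordinate; no
progressive multiple alignment is attempted. Region filtering assigns a
site to a window iff its 5′ column lies inside the window, so a helix
window selects exactly its own pairs and per-helix counts over a partition
of the molecule sum to the unrestricted count.

## The number-code barcode

A structure region is rendered as one digit per *pair-or-unpaired-column*:
each base pair contributes its code (1–6 by identity and orientation, 7 if
its residues cannot pair) once, at its 5′ column, with the 3′ column
omitted; unpaired and gapped columns contribute 8. Coding each pair once
keeps the barcode compact, and the orientation distinction (A–U = 1 vs
U–A = 2) preserves the information the omitted 3′ column would carry; the
column map retains the partner column for traceability.

Barcode comparison walks columns and annotates `same`, `CBC`, `HCBC`,
`I/D` (exactly one digit is 8) or `other` (any difference touching a
mismatch digit 7 — not compensatory by definition). When the two
structures disagree on *which* columns pair, their emitted column sets
differ; the comparison then walks the union of emitted columns, a 3′ pair
column inheriting its pair's digit and an absent column reading as 8. On
equal-topology strains the barcode diff and the event engine are two
independent routes to the same CBC/HCBC counts, and the tests assert they
agree.

## Species delineation

The criterion: strains separated by ≥ `threshold` CBCs (default 1) in the
compared region are different species. Conspecificity by zero CBCs is not
a transitive relation, so groups are the connected components of the graph
joining below-threshold pairs; when a component contains an
above-threshold pair the package warns rather than splits (the data sets
this method targets are far from that regime, but the behavior must be
defined). HCBC counts appear in every report but never drive a split.

## Synthetic families

The generator builds an ITS-2-like template — by default four sequential
hairpins (stems of 7, 6, 10 and 5 pairs with loops of 4–6 nt, mostly
Watson–Crick with ~12 % wobbles), 4-nt spacers, and a designated 12-nt
unpaired variable region before the last helix, ~110 nt in total. A family
is two groups of three strains (mirroring the six-strain study design):
group 1 descends from the template, each further group from an ancestor
carrying planted between-group events — default 2 CBCs, 2 HCBCs and 2
neutral substitutions — while strains within a group add only 1 neutral
substitution each at unpaired columns. Planted events never touch the same
pair or column twice (an over-subscribed spec raises), so recovered counts
equal planted counts exactly; optional indels act inside the variable
region and shift downstream coordinates consistently. The manifest records
every edit plus the expected pairwise CBC/HCBC matrices, derived from the
ancestors' per-pair states by the definitional rules, and the expected
partition.

The SSU fixture plants an exact number of variable columns (default 15)
into an otherwise invariant 6 × 1800 alignment and, optionally, an
intron-like block (default 400 columns after position 516) present
identically in carrier strains and gapped elsewhere. Insertion-block
detection requires a run of ≥ 50 carrier-only columns by default — far
above indel scatter, far below any group I intron.

What the generator does *not* emulate: substitution-model evolution (no
rates, no transition/transversion bias), thermodynamic plausibility of
stems, intra-group structural polymorphism, and alignment ambiguity in the
variable region. Passing the recovery tests therefore shows the pipeline
is exact on cleanly homologous structures; on real data the binding
constraint is the quality of the folding and the structural alignment,
both of which the package deliberately treats as exchangeable inputs
(CT/Vienna files, aligned FASTA).

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere (CT convention); alignment
  columns are 0-based internally and printed 1-based.
* Structures must be nested: pseudoknots and base triples are rejected at
  load time because column mapping and barcode emission assume nestedness.
* IUPAC ambiguity codes other than N are rejected at load with the
  offending position; N is accepted and classified mismatch.
* All generator randomness flows through a single `numpy` Generator seeded
  explicitly; analysis code contains no randomness at all, and re-running
  any analysis on identical inputs is byte-identical.
* Problem sizes in tests and the acceptance script (≈110-nt molecules,
  6-strain families, 6 × 2200 SSU alignments) were chosen so the whole
  validation runs in seconds while exercising every code path at the same
  strain/group/event counts as the motivating study design.

## Known limitations

* The star alignment inherits any reference-specific bias; with highly
  diverged strains a different reference can change gap placement. Users
  can supply an external structural alignment instead.
* Barcode diffs between strains of different helix topology depend on the
  union-walk convention above; the event engine is the authoritative
  counter in that regime.
* Group-consensus barcodes (majority rule) are not built in; comparisons
  are per strain pair.
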